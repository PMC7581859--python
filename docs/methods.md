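# Methods

`bgamap` maps category-selective visual cortex from intracranial EEG (iEEG):
it estimates the broadband gamma activity (BGA, 50–150 Hz) evoked by scene
and object photographs on every bipolar channel, tests each channel for a
response and for a category preference, measures when the two categories
become distinguishable, clusters the selective sites in MNI space, and
quantifies single-trial discriminability. A matched simulator generates
synthetic sessions with planted ground truth so that every stage can be
validated quantitatively.

## Stimulation protocol (generator default)

Subjects view photographs in a rapid serial design:

| parameter | value |
| --- | --- |
| categories | scenes, objects, faces: 100 unique × 2 repeats each |
| target category | fruit/vegetable: 25 unique × 2 repeats (keypress) |
| total stimuli | 650 |
| stimulus duration | 300 ms |
| stimulus onset asynchrony | 1,100 ms |
| block structure | 5 stimuli per block, 3-s pauses between blocks |

Picture order is randomised without immediate repeats of the same picture.
Keypress trials (target hits and false alarms) are later excluded from
analysis. A scaled-down variant (`small_protocol`) keeps the identical
structure with fewer unique pictures for fast simulation studies.

## Signal model of the simulator

Each bipolar channel is simulated as 1/f-spectrum Gaussian noise whose
50–150 Hz component is multiplied by an event-locked gain profile:

- gain pulses start 100–400 ms after onset of pictures of the channel's
  preferred category (uniform draw, or fixed), last 100–500 ms, and peak at
  +10–60% with 50-ms raised-cosine ramps;
- optional interictal spikes: 70-ms biphasic transients at 8× the channel
  standard deviation, Poisson-distributed, recorded in an annotations table;
- contact-level signals are constructed by telescoping sums so that the
  bipolar montage recovers each planted source exactly, and contact
  positions are chosen so that pair midpoints equal the specified MNI
  coordinates. Channel geometry can be planted around known scene-/object-
  selective centroids (parahippocampal, occipital and medial place areas;
  lateral occipital sites).

Fidelity and limits: the simulator reproduces the *statistical* structure
the analysis depends on (1/f background, multiplicative band-limited gain,
trial timing, artifacts, spatial clusters) but is not a biophysical model —
no volume conduction, no cross-channel correlation, no non-stationarity
beyond the planted effects. It is a test bed, not a forward model.

## Analysis pipeline

1. **Resampling** to 512 Hz (polyphase; upsampling is refused).
2. **Bipolar montage**: adjacent contacts on each shaft are subtracted
   (contact *i* − contact *i+1*); the derived channel inherits the pair
   midpoint, the worse tissue label of the pair (heterotopic > white > gray)
   and the OR of the epileptic flags.
3. **Trial exclusion** (first matching reason wins): epochs extending past
   the recording edge; keypress trials (channel-independent); per-channel
   overlap with a spike annotation on the bipolar channel or either
   constituent contact.
4. **BGA estimation**: the 50–150 Hz range is split into twenty 5-Hz bands;
   each band is filtered (3rd-order Butterworth, zero-phase forward-backward),
   Hilbert-transformed to its amplitude envelope, downsampled to 64 Hz, and
   divided by its session mean (computed with 1 s trimmed at each edge) —
   this normalisation whitens the 1/f spectrum so every band contributes
   equally. The BGA is the across-band average × 100 (session mean ≈ 100%).
5. **Epoching**: 64 samples per trial at onset + k/64 s for k = −13…50
   (−203 … +781 ms); the mean of the three samples in [−50, 0) ms is
   subtracted, so values read as % change from the immediate pre-stimulus
   baseline.
6. **Detection**: per channel and category, each post-stimulus sample is
   compared with the per-trial pre-stimulus mean by a two-sided Wilcoxon
   rank-sum test (exact for small tie-free samples, otherwise normal
   approximation with tie and continuity corrections). Each p-value is
   replaced by the maximum over a forward sliding window of 6 samples
   (93.75 ms; truncated at the series end), requiring sustained effects.
   Benjamini–Hochberg FDR correction at q = 0.05 is applied over the pooled
   channels × time family, per category. Channels need ≥ 10 usable trials
   per category; active channels are classed *scene-only*, *object-only* or
   *both*.
7. **Post-detection filters** (exclusions from the *active* set, not from
   testing): channels in white matter or heterotopic cortex, and channels
   whose response peaks in the final 100 ms of the epoch while still rising
   ("late"). Channels flagged epileptic are kept by default (their spike
   trials were already excluded).
8. **Selectivity**: scene vs object trials are compared samplewise with the
   same rank-sum / sliding-window / FDR machinery (a separate FDR family).
   The preferred category is the sign of the difference at the most extreme
   significant sample; channels significant in both directions are flagged
   *mixed*. Timing measures: `tsig` (first significant sample, ms), `lensig`
   (number of significant samples × 15.625 ms), `t90` (first time the
   preferred-direction difference reaches 90% of its maximum).
9. **Response measures** per active channel and category: magnitude (peak of
   the trial-mean response), response `t90`, and the late flag.
10. **Clustering**: selective sites are pooled across hemispheres (x → |x|)
    and clustered by K-means under the city-block (L1) metric with
    coordinate-wise **median** centroids and greedy D²-weighted seeding.
    Candidate k (2…8) are ranked by mean silhouette (L1); a candidate is
    accepted only if 20 independently seeded runs all converge to the
    identical partition (up to relabeling); otherwise the candidate with the
    highest fraction of matching runs is returned flagged unstable. The
    partition's explained spatial variance is the conventional
    sum-of-squares ratio 1 − SS_within/SS_total (an L1 variant is available).
11. **ROC**: for each selective channel, the area under the ROC curve
    (Mann–Whitney U / n₁n₂, ties 0.5) between preferred and non-preferred
    single-trial responses is computed at every post-stimulus sample; the
    maximum and its latency summarise discriminability.

## Numerical choices and design decisions

- Zero-phase filtering (`sosfiltfilt`) avoids group delay in onset-latency
  measures; Hilbert transforms are padded to fast FFT lengths.
- The detection and selectivity tests are corrected as *separate* FDR
  families: they answer different questions and pooling them would couple
  their thresholds.
- The sliding max-p window runs forward and truncates at the epoch end, so
  a sustained effect ending at the epoch boundary is not penalised.
- Explained variance is reported with the L2 (sum-of-squares) decomposition
  even though clustering is L1: "fraction of spatial variance" is a
  variance-based quantity; the L1 analogue is provided as an option.
- Greedy k-means++ seeding (2 + ⌊log k⌋ candidates per seed) is used because
  single-candidate seeding occasionally converges to a near-degenerate local
  optimum, which the all-runs-identical stability rule would misread as
  instability of the data rather than of the optimiser.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; a pipeline run is byte-reproducible.

## Problem sizes used in validation

- Unit tests: sessions of ~10 bipolar channels, 15 unique pictures/category.
- Parameter recovery: 20 sessions, planted +40% gain at 200 ms, 50 trials
  per category → detection sensitivity and onset-recovery error.
- False-positive control: 20 sessions × 200 null channels (4,000 channel
  decisions) → realised false-discovery proportion vs q.
- Cluster recovery: 3 planted centroids ≥ 40 mm apart, 4 mm spread,
  15 sites each.
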