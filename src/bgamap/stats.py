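"""Response detection, category selectivity, and timing statistics.

Detection compares, per channel and stimulus category, each post-stimulus BGA
sample against the per-trial prestimulus mean with a two-sided Wilcoxon
rank-sum test across trials.  As a conservative guard against isolated
low p-values, every time point is assigned the *maximum* p over a forward
sliding window of six samples (93.75 ms at 64 Hz), so a point counts as
significant only when six consecutive samples are.  Window-adjusted p-values
are then corrected by the Benjamini-Hochberg false-discovery-rate step-up
pooled over all channels and post-stimulus time points of one test family
(each category's detection, and the scene-vs-object contrast, are separate
families, all at q = 0.05).

Selective channels get three timing measures on the 64 Hz grid: *tsig*, the
first significant time of the between-category difference; *lensig*, the
total significant duration; and *t90*, the first time the preferred-direction
difference reaches 90% of its maximum.  Response magnitude is the maximum
positive trial-mean power change after onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, norm, rankdata
from statsmodels.stats.multitest import multipletests

from .envelope import EpochSet

__all__ = [
    "SignificanceMap",
    "DetectionResult",
    "SelectivityResult",
    "ranksum_p",
    "sliding_max_p",
    "fdr_select",
    "detect_responses",
    "assess_selectivity",
    "response_measures",
    "discrimination_timing",
    "bin_average",
    "SLIDING_WINDOW",
]

SLIDING_WINDOW = 6  # samples; 6 / 64 Hz = 93.75 ms
DEFAULT_Q = 0.05
MIN_TRIALS = 10
LATE_WINDOW_S = 0.100  # "still increasing at 800 ms" check uses the final 100 ms


@dataclass
class SignificanceMap:
    """Raw, window-adjusted and FDR-thresholded p-values (channels x time)."""

    raw_p: np.ndarray
    adj_p: np.ndarray
    significant: np.ndarray
    q: float
    window: int


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for small tie-free samples, otherwise the normal approximation with
    tie and continuity corrections.  Two identical constant samples give 1.0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def _ranksum_p_block(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised two-sided rank-sum over the last axis.

    ``x`` and ``y`` are stacks of samples (…, nx) and (…, ny); returns p of
    shape (…,).  Normal approximation with tie and continuity corrections —
    used for the channels x time detection grids, where samples are large.
    """
    nx, ny = x.shape[-1], y.shape[-1]
    combined = np.concatenate([x, y], axis=-1)
    ranks = rankdata(combined, axis=-1)
    r_x = ranks[..., :nx].sum(axis=-1)
    u = r_x - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    n = nx + ny
    # tie correction on the variance
    sorted_c = np.sort(combined, axis=-1)
    new_val = np.concatenate(
        [np.ones(sorted_c.shape[:-1] + (1,), bool), np.diff(sorted_c, axis=-1) != 0], axis=-1
    )
    tie_term = np.zeros(u.shape)
    if not new_val.all():
        # run lengths via cumulative counts of distinct values;
        # sum (t^3 - t) over tie groups, looping over group ids
        grp = np.cumsum(new_val, axis=-1)
        for g in range(1, int(grp[..., -1].max()) + 1):
            t = (grp == g).sum(axis=-1)
            tie_term += t**3 - t
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u - mu) - 0.5) / sd
    z = np.where(sd == 0, 0.0, np.maximum(z, 0.0))
    p = 2 * norm.sf(z)
    return np.where(sd == 0, 1.0, np.minimum(p, 1.0))


def sliding_max_p(p: np.ndarray, w: int = SLIDING_WINDOW) -> np.ndarray:
    """Forward sliding-window maximum: ``adj[t] = max(p[t .. t+w-1])``.

    The window truncates at the end of the series; w larger than the series
    yields the global maximum everywhere.  Works on the last axis.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    p = np.asarray(p, float)
    n = p.shape[-1]
    out = np.empty_like(p)
    for t in range(n):
        out[..., t] = p[..., t : min(t + w, n)].max(axis=-1)
    return out


def fdr_select(p: np.ndarray, q: float = DEFAULT_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up over the pooled family of p-values.

    The whole array is one family (all channels x all time points of one
    test); returns a boolean mask of the same shape.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return np.zeros(p.shape, bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def _class_label(active_scene: bool, active_object: bool) -> str:
    if active_scene and active_object:
        return "both"
    if active_scene:
        return "scene-only"
    if active_object:
        return "object-only"
    return "none"


@dataclass
class DetectionResult:
    """Per-category responsiveness of every channel."""

    categories: tuple[str, ...]
    maps: dict[str, SignificanceMap]
    active: dict[str, np.ndarray]  # category -> bool per channel
    analyzable: np.ndarray  # bool per channel (enough usable trials)
    n_trials: dict[str, np.ndarray]
    classes: np.ndarray  # both | scene-only | object-only | none

    @property
    def any_active(self) -> np.ndarray:
        out = np.zeros_like(self.analyzable)
        for cat in self.categories:
            out |= self.active[cat]
        return out


def detect_responses(
    epochs: EpochSet,
    categories: tuple[str, str] = ("scene", "object"),
    q: float = DEFAULT_Q,
    window: int = SLIDING_WINDOW,
    min_trials: int = MIN_TRIALS,
) -> DetectionResult:
    """Flag channels with a significant post-stimulus BGA change per category.

    Per channel and category, the per-trial prestimulus mean (all samples
    before 0) is compared with every post-stimulus sample by rank-sum across
    trials; p-values pass the sliding-max window and one pooled BH correction
    per category (channels x time family).  A channel is *active* for a
    category iff any post-stimulus sample survives.
    """
    n_ch = epochs.data.shape[0]
    post = epochs.post
    n_post = len(epochs.post_times)
    maps: dict[str, SignificanceMap] = {}
    active: dict[str, np.ndarray] = {}
    n_trials: dict[str, np.ndarray] = {}
    analyzable = np.ones(n_ch, bool)
    for cat in categories:
        raw = np.ones((n_ch, n_post))
        counts = np.zeros(n_ch, int)
        for ch in range(n_ch):
            tr = epochs.trials_of(cat, ch)
            counts[ch] = tr.size
            if tr.size < min_trials:
                continue
            d = epochs.data[ch, tr]  # trials x samples
            baseline = d[:, epochs.prestim].mean(axis=1)  # per-trial prestim mean
            values = d[:, post]  # trials x n_post
            raw[ch] = _ranksum_p_block(
                np.broadcast_to(baseline, (n_post, tr.size)),
                values.T,
            )
        adj = sliding_max_p(raw, window)
        ok = counts >= min_trials
        analyzable &= ok  # analyzable only if every category has enough trials
        sig = np.zeros_like(adj, bool)
        if ok.any():
            sig[ok] = fdr_select(adj[ok], q)
        maps[cat] = SignificanceMap(raw, adj, sig, q, window)
        active[cat] = sig.any(axis=1) & ok
        n_trials[cat] = counts
    classes = np.array(
        [
            _class_label(active[categories[0]][ch], active[categories[1]][ch])
            for ch in range(n_ch)
        ],
        object,
    )
    return DetectionResult(
        categories=categories,
        maps=maps,
        active=active,
        analyzable=analyzable,
        n_trials=n_trials,
        classes=classes,
    )


@dataclass
class SelectivityResult:
    """Scene-vs-object contrast per channel."""

    pair: tuple[str, str]
    map: SignificanceMap
    direction: np.ndarray  # pair[0] | pair[1] | 'none' per channel
    mixed: np.ndarray  # bool: significant samples of both signs
    difference: np.ndarray  # channels x post samples, mean(pair0) - mean(pair1)
    tsig: np.ndarray  # ms, NaN when no significant sample
    lensig: np.ndarray  # ms
    t90: np.ndarray  # ms

    @property
    def selective(self) -> np.ndarray:
        return self.direction != "none"


def assess_selectivity(
    epochs: EpochSet,
    pair: tuple[str, str] = ("scene", "object"),
    q: float = DEFAULT_Q,
    window: int = SLIDING_WINDOW,
    min_trials: int = MIN_TRIALS,
) -> SelectivityResult:
    """Classify channels as scene- or object-selective.

    Per post-stimulus sample the two categories' single-trial responses are
    compared by rank-sum; sliding-max window and one pooled BH family over
    channels x time.  Direction is the sign of the mean difference at the
    significant sample of maximal absolute difference; channels whose
    significant samples carry both signs are additionally flagged mixed.
    """
    n_ch = epochs.data.shape[0]
    post = epochs.post
    n_post = len(epochs.post_times)
    raw = np.ones((n_ch, n_post))
    diff = np.zeros((n_ch, n_post))
    ok = np.zeros(n_ch, bool)
    for ch in range(n_ch):
        ta = epochs.trials_of(pair[0], ch)
        tb = epochs.trials_of(pair[1], ch)
        if ta.size < min_trials or tb.size < min_trials:
            continue
        ok[ch] = True
        a = epochs.data[ch, ta][:, post]
        b = epochs.data[ch, tb][:, post]
        diff[ch] = a.mean(axis=0) - b.mean(axis=0)
        raw[ch] = _ranksum_p_block(a.T, b.T)
    adj = sliding_max_p(raw, window)
    sig = np.zeros_like(adj, bool)
    if ok.any():
        sig[ok] = fdr_select(adj[ok], q)
    direction = np.full(n_ch, "none", object)
    mixed = np.zeros(n_ch, bool)
    tsig = np.full(n_ch, np.nan)
    lensig = np.full(n_ch, np.nan)
    t90 = np.full(n_ch, np.nan)
    fs = epochs.fs
    for ch in range(n_ch):
        if not sig[ch].any():
            continue
        idx = np.flatnonzero(sig[ch])
        best = idx[np.argmax(np.abs(diff[ch, idx]))]
        direction[ch] = pair[0] if diff[ch, best] >= 0 else pair[1]
        signs = np.sign(diff[ch, idx])
        mixed[ch] = (signs > 0).any() and (signs < 0).any()
        sgn = 1.0 if direction[ch] == pair[0] else -1.0
        tsig[ch], lensig[ch], t90[ch] = discrimination_timing(
            sig[ch], sgn * diff[ch], fs=fs
        )
    return SelectivityResult(
        pair=pair,
        map=SignificanceMap(raw, adj, sig, q, window),
        direction=direction,
        mixed=mixed,
        difference=diff,
        tsig=tsig,
        lensig=lensig,
        t90=t90,
    )


def discrimination_timing(
    sig: np.ndarray, preferred_diff: np.ndarray, fs: float = 64.0
) -> tuple[float, float, float]:
    """Timing measures (ms) from a significance mask and a difference series.

    ``preferred_diff`` must be oriented so the preferred direction is
    positive.  Returns ``(tsig, lensig, t90)``: first significant time,
    total significant duration (count x sample period), and the first time
    the difference reaches 90% of its maximum.  tsig/lensig are NaN when no
    sample is significant.
    """
    sig = np.asarray(sig, bool)
    preferred_diff = np.asarray(preferred_diff, float)
    period_ms = 1000.0 / fs
    if sig.any():
        tsig = float(np.flatnonzero(sig)[0]) * period_ms
        lensig = float(sig.sum()) * period_ms
    else:
        tsig = float("nan")
        lensig = float("nan")
    peak = preferred_diff.max()
    if peak > 0:
        t90 = float(np.flatnonzero(preferred_diff >= 0.9 * peak)[0]) * period_ms
    else:
        t90 = float("nan")
    return tsig, lensig, t90


def response_measures(
    epochs: EpochSet, channel: int, category: str, fs: float | None = None
) -> tuple[float, float, bool]:
    """Magnitude, response time and late-response flag for one channel/category.

    magnitude: maximum positive trial-mean power change after onset (%, 0 when
    the mean response never goes positive); response t90: first time (ms) the
    trial mean reaches 90% of that maximum (NaN when magnitude is 0); late
    flag: the maximum falls in the final 100 ms *and* the mean slope over the
    final 100 ms is positive — i.e. the response is still rising at the end
    of the epoch and its magnitude cannot be determined.
    """
    fs = fs or epochs.fs
    tr = epochs.trials_of(category, channel)
    mean = epochs.data[channel, tr][:, epochs.post].mean(axis=0)
    times_ms = epochs.post_times * 1000.0
    peak = mean.max()
    magnitude = max(0.0, float(peak))
    if magnitude > 0:
        t90 = float(times_ms[np.flatnonzero(mean >= 0.9 * magnitude)[0]])
    else:
        t90 = float("nan")
    late_sel = times_ms >= times_ms[-1] - LATE_WINDOW_S * 1000.0
    argmax_late = bool(late_sel[int(np.argmax(mean))])
    tail = mean[late_sel]
    slope = float(np.polyfit(times_ms[late_sel], tail, 1)[0]) if tail.size >= 2 else 0.0
    late = argmax_late and slope > 0
    return magnitude, t90, late


def bin_average(
    epochs: EpochSet,
    categories: tuple[str, ...] = ("scene", "object"),
    bin_width: float = 0.100,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-mean response averaged in consecutive post-stimulus time bins.

    Returns ``(means, edges)`` with means shaped channels x categories x bins
    (8 bins of 100 ms over 0-800 ms by default) — the table consumed by
    downstream repeated-measures ANOVAs, which are outside this package.
    """
    t_post = epochs.post_times
    dt = 1.0 / epochs.fs
    span = (epochs.times[-1] + dt) - t_post[0]
    n_bins = span / bin_width
    # the post-stimulus grid nominally covers [0, 800) ms but its last sample
    # sits one grid step short; accept a within-one-sample mismatch
    if abs(n_bins - round(n_bins)) > dt / bin_width + 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide the {span:.3f} s span")
    n_bins = int(round(n_bins))
    bin_idx = np.minimum((t_post / bin_width).astype(int), n_bins - 1)
    n_ch = epochs.data.shape[0]
    out = np.full((n_ch, len(categories), n_bins), np.nan)
    for ci, cat in enumerate(categories):
        for ch in range(n_ch):
            tr = epochs.trials_of(cat, ch)
            if tr.size == 0:
                continue
            mean = epochs.data[ch, tr][:, epochs.post].mean(axis=0)
            for b in range(n_bins):
                out[ch, ci, b] = mean[bin_idx == b].mean()
    edges = np.arange(n_bins + 1) * bin_width
    return out, edges
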