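"""Synthetic stereo-EEG sessions with known ground truth.

The generator emulates what the analysis assumes about real depth-electrode
recordings:

* background activity is Gaussian noise with a 1/f power spectral density,
  so that the per-band whitening step of the gamma-envelope pipeline has the
  spectral decay it was designed to compensate;
* a stimulus-responsive channel shows a *multiplicative* increase of its
  50-150 Hz amplitude, time-locked to events of the categories it responds
  to, with a raised-cosine rise and fall (50 ms ramps) around a plateau at
  ``1 + peak_gain`` times the session-mean gamma amplitude;
* interictal epileptiform spikes are brief (70 ms) biphasic high-amplitude
  transients at Poisson times, recorded as annotations so that the epoch
  rejection rule can be exercised (the spike detector itself is an external
  clinical tool whose output the pipeline consumes);
* electrode contacts live in MNI space; geometries can be planted around
  known cluster centroids to test the spatial clustering stage.

Effects are specified per *bipolar* channel — the unit the analysis operates
on.  The simulator emits a contact-level recording by telescoping sums
(``contact_i = source_i + contact_{i+1}`` along each shaft), so that the
bipolar montage recovers exactly the planted source signals and the planted
effect sizes are exact at the analysis level.  Contact coordinates are chosen
so that each adjacent-pair midpoint equals the requested MNI position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq

from .io_formats import Recording

__all__ = [
    "EffectSpec",
    "ChannelSpec",
    "GroundTruth",
    "SimulatedSession",
    "simulate_recording",
    "plant_geometry",
]

GAMMA_BAND = (50.0, 150.0)
_RAMP_S = 0.050  # raised-cosine rise/fall of the gain pulse
_SPIKE_DUR_S = 0.070
_SPIKE_AMP_SD = 8.0  # spike amplitude in units of background SD


@dataclass(frozen=True)
class EffectSpec:
    """Event-locked gamma response: gain pulse relative to stimulus onset."""

    onset: float = 0.2  # s after stimulus
    duration: float = 0.3  # s
    peak_gain: float = 0.4  # fractional amplitude increase of 50-150 Hz content

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("effect onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("effect duration must be > 0")
        if self.peak_gain < 0:
            raise ValueError("peak_gain must be >= 0")


@dataclass(frozen=True)
class ChannelSpec:
    """One simulated bipolar channel (= adjacent contact pair)."""

    name: str
    shaft: str
    mni: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region: str = "n/a"
    epileptic: bool = False
    tissue: str = "gray"
    effects: dict[str, EffectSpec] = field(default_factory=dict)
    spike_rate: float = 0.0  # interictal spikes / s

    def __post_init__(self) -> None:
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.tissue not in ("gray", "white", "heterotopic"):
            raise ValueError(f"unknown tissue label {self.tissue!r}")


@dataclass
class GroundTruth:
    """Planted truth per simulated bipolar channel."""

    channel: list[str]
    label: list[str]  # none | scene | object | both (w.r.t. the analysed pair)
    active_categories: dict[str, list[str]]
    true_onset: dict[str, dict[str, float]]  # channel -> category -> onset s
    cluster_id: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "label": self.label,
            "active_categories": self.active_categories,
            "true_onset": self.true_onset,
            "cluster_id": self.cluster_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            channel=list(d["channel"]),
            label=list(d["label"]),
            active_categories={k: list(v) for k, v in d["active_categories"].items()},
            true_onset={k: dict(v) for k, v in d["true_onset"].items()},
            cluster_id={k: int(v) for k, v in d.get("cluster_id", {}).items()},
        )


@dataclass
class SimulatedSession:
    """A simulated recording, its (time-shifted) events, annotations and truth."""

    recording: Recording
    events: pd.DataFrame
    annotations: pd.DataFrame  # channel, onset, duration, label
    ground_truth: GroundTruth


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Gaussian noise with PSD proportional to 1/f above 1 Hz, unit variance."""
    white = rng.standard_normal(n)
    spec = rfft(white)
    f = rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    shaping[0] = 0.0  # no DC
    x = irfft(spec * shaping, n=n)
    return x / x.std()


def _band_split(x: np.ndarray, fs: float, band: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Split ``x`` into its ``band`` component and the remainder (FFT mask)."""
    spec = rfft(x)
    f = rfftfreq(x.size, d=1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    in_band = irfft(spec * mask, n=x.size)
    return in_band, x - in_band


def _gain_profile(
    t: np.ndarray,
    events: pd.DataFrame,
    effects: dict[str, EffectSpec],
) -> np.ndarray:
    """Multiplicative gamma gain over time: 1 plus raised-cosine pulses."""
    g = np.zeros_like(t)
    for trial_type, eff in effects.items():
        if eff.peak_gain == 0:
            continue
        onsets = events.loc[events["trial_type"] == trial_type, "onset"].to_numpy()
        for ev_onset in onsets:
            start = ev_onset + eff.onset
            ramp = min(_RAMP_S, eff.duration / 2)
            # raised-cosine rise over [start, start+ramp], plateau, fall
            rel = t - start
            rise = (rel >= 0) & (rel < ramp)
            plateau = (rel >= ramp) & (rel < eff.duration - ramp)
            fall = (rel >= eff.duration - ramp) & (rel < eff.duration)
            pulse = np.zeros_like(t)
            pulse[rise] = 0.5 * (1 - np.cos(np.pi * rel[rise] / ramp))
            pulse[plateau] = 1.0
            pulse[fall] = 0.5 * (1 - np.cos(np.pi * (eff.duration - rel[fall]) / ramp))
            g += eff.peak_gain * pulse
    return 1.0 + g


def _spike_waveform(fs: float) -> np.ndarray:
    """70-ms biphasic transient, unit peak amplitude."""
    n = int(round(_SPIKE_DUR_S * fs))
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * t / _SPIKE_DUR_S) * np.hanning(n)


def _truth_label(active: list[str], pair: tuple[str, str] = ("scene", "object")) -> str:
    a, b = pair
    has_a, has_b = a in active, b in active
    if has_a and has_b:
        return "both"
    if has_a:
        return a
    if has_b:
        return b
    return "none"


def simulate_recording(
    events: pd.DataFrame,
    channels: list[ChannelSpec],
    fs: float = 512.0,
    seed: int = 0,
    pad: float = 2.0,
    amplitude_v: float = 50e-6,
) -> SimulatedSession:
    """Simulate a contact-level recording realising the planted channel specs.

    Parameters
    ----------
    events
        Protocol events table (onsets starting at 0); returned shifted by
        ``pad`` seconds so epochs never touch the recording edges.
    channels
        Bipolar-channel specifications; entries sharing a ``shaft`` become
        adjacent sources on one physical shaft (m sources -> m+1 contacts).
    fs
        Sampling rate; 512 Hz recommended (>= 300 Hz required so the gamma
        band exists below Nyquist).
    seed
        Seeds all randomness (noise, spikes); same seed => bit-identical output.
    """
    if not channels:
        raise ValueError("channel list is empty")
    if len(events) == 0:
        raise ValueError("events table is empty")
    if fs < 2 * GAMMA_BAND[1]:
        raise ValueError(f"fs={fs} too low for the {GAMMA_BAND} Hz band")

    events = events.copy()
    events["onset"] = events["onset"] + pad
    duration = float(events["onset"].max()) + 2.0 + pad
    if duration <= 0:
        raise ValueError("negative recording duration")
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(channels) + 64)

    # simulate the bipolar source of each spec channel
    sources = np.empty((len(channels), n))
    annotations: list[dict] = []
    truth_active: dict[str, list[str]] = {}
    truth_onset: dict[str, dict[str, float]] = {}
    labels: list[str] = []
    shaft_order: dict[str, list[int]] = {}
    for i, ch in enumerate(channels):
        rng = np.random.default_rng(child_seeds[i])
        noise = _one_over_f_noise(rng, n, fs)
        gamma, rest = _band_split(noise, fs, GAMMA_BAND)
        g = _gain_profile(t, events, ch.effects)
        sig = rest + g * gamma
        if ch.spike_rate > 0:
            n_spikes = rng.poisson(ch.spike_rate * duration)
            wf = _spike_waveform(fs) * _SPIKE_AMP_SD * sig.std()
            for t0 in np.sort(rng.uniform(0, duration - _SPIKE_DUR_S, n_spikes)):
                i0 = int(round(t0 * fs))
                sig[i0 : i0 + wf.size] += wf[: n - i0]
                annotations.append(
                    {"channel": ch.name, "onset": t0, "duration": _SPIKE_DUR_S, "label": "spike"}
                )
        sources[i] = sig * amplitude_v
        active = sorted(c for c, e in ch.effects.items() if e.peak_gain > 0)
        truth_active[ch.name] = active
        truth_onset[ch.name] = {c: ch.effects[c].onset for c in active}
        labels.append(_truth_label(active))
        shaft_order.setdefault(ch.shaft, []).append(i)

    # telescope sources into contacts per shaft; name contacts <shaft><k>
    contact_names: list[str] = []
    contact_rows: list[dict] = []
    contact_signals: list[np.ndarray] = []
    rng_ref = np.random.default_rng(child_seeds[len(channels)])
    for shaft, idxs in shaft_order.items():
        m = len(idxs)
        # reference contact: independent low-amplitude noise (white-matter ref)
        ref = _one_over_f_noise(rng_ref, n, fs) * amplitude_v * 0.1
        sigs = [ref]
        for i in reversed(idxs):
            sigs.append(sigs[-1] + sources[i])
        sigs.reverse()  # sigs[k] = contact k (deepest pair source first)
        # positions: midpoints of adjacent contacts equal the spec MNI exactly
        mnis = [np.asarray(channels[i].mni, float) for i in idxs]
        if m > 1:
            axis = mnis[-1] - mnis[0]
            norm = np.linalg.norm(axis)
            axis = axis / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        else:
            axis = np.array([1.0, 0.0, 0.0])
        pos = [mnis[0] - 1.75 * axis]
        for mid in mnis:
            pos.append(2 * mid - pos[-1])
        for k in range(m + 1):
            src = channels[idxs[min(k, m - 1)]]
            contact_names.append(f"{shaft}{k + 1}")
            contact_rows.append(
                {
                    "name": f"{shaft}{k + 1}",
                    "shaft": shaft,
                    "contact": k + 1,
                    "x": round(float(pos[k][0]), 1),
                    "y": round(float(pos[k][1]), 1),
                    "z": round(float(pos[k][2]), 1),
                    "region": src.region,
                    "epileptic": src.epileptic,
                    "tissue": src.tissue,
                }
            )
            contact_signals.append(sigs[k])

    electrodes = pd.DataFrame(contact_rows)
    channels_tbl = electrodes[["name", "shaft", "contact"]].copy()
    channels_tbl["status"] = "good"
    rec = Recording(
        signal=np.vstack(contact_signals),
        fs=fs,
        channels=channels_tbl,
        electrodes=electrodes,
    )

    # annotation channel names at the bipolar level: <shaft><k>-<shaft><k+1>
    bip_name = {}
    for shaft, idxs in shaft_order.items():
        for k, i in enumerate(idxs):
            bip_name[channels[i].name] = f"{shaft}{k + 1}-{shaft}{k + 2}"
    ann = pd.DataFrame(annotations, columns=["channel", "onset", "duration", "label"])
    if len(ann):
        ann["channel"] = ann["channel"].map(bip_name)
        ann = ann.sort_values(["onset", "channel"], kind="stable").reset_index(drop=True)

    truth = GroundTruth(
        channel=[bip_name[ch.name] for ch in channels],
        label=labels,
        active_categories={bip_name[k]: v for k, v in truth_active.items()},
        true_onset={bip_name[k]: v for k, v in truth_onset.items()},
    )
    return SimulatedSession(recording=rec, events=events, annotations=ann, ground_truth=truth)


def plant_geometry(
    centroids: list[tuple[float, float, float]],
    n_per_cluster: int,
    spread_mm: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw electrode coordinates isotropically around planted centroids.

    Returns ``(coords, labels)`` where ``coords`` is (n_clusters *
    n_per_cluster) x 3 in MNI mm and ``labels`` the true cluster index of
    each point.
    """
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    if spread_mm < 0:
        raise ValueError("spread_mm must be >= 0")
    rng = np.random.default_rng(seed)
    coords = []
    labels = []
    for k, c in enumerate(centroids):
        pts = np.asarray(c, float) + rng.normal(0.0, spread_mm, size=(n_per_cluster, 3))
        coords.append(pts)
        labels.extend([k] * n_per_cluster)
    return np.vstack(coords), np.asarray(labels)
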