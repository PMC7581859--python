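"""Broadband gamma activity (BGA) estimation and epoching.

Broadband gamma power (50-150 Hz) correlates with local population firing and
with the fMRI BOLD signal, which makes it the signal of interest for mapping
category-selective cortex from depth recordings.  The estimator:

1. band-pass filters the whole session in consecutive non-overlapping 5-Hz
   bands (third-order Butterworth, zero phase) — 20 bands over 50-150 Hz;
2. takes each band's Hilbert amplitude envelope;
3. downsamples each envelope to 64 Hz (anti-aliased polyphase);
4. divides each band envelope by its session mean, channel-wise — this
   whitens the 1/f spectral decay so every band contributes equally;
5. averages the 20 normalised envelopes and multiplies by 100, giving a
   single BGA power series per channel in percent of the session mean.

The BGA series is epoched from -200 to +800 ms around each stimulus onset and
the mean of the -50-0 ms prestimulus samples is subtracted per epoch, so
epoch values are percent power change relative to the immediate prestimulus
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt

from .preprocess import BipolarRecording, TrialMask

__all__ = [
    "EnvelopeSeries",
    "EpochSet",
    "band_edges",
    "band_envelope",
    "bga_envelope",
    "epoch_envelope",
    "EPOCH_K_MIN",
    "EPOCH_K_MAX",
    "FS_ENV",
]

FS_ENV = 64.0
# epoch grid: samples k/64 s relative to onset, k = -13 .. 50 (64 samples,
# covering about [-200, 800) ms); baseline-subtraction window [-50, 0) ms
EPOCH_K_MIN = -13
EPOCH_K_MAX = 50
BASELINE_WINDOW = (-0.050, 0.0)
EDGE_TRIM_S = 1.0  # session-mean support excludes filter warm-up at both ends


@dataclass
class EnvelopeSeries:
    """Per-channel BGA power at 64 Hz, percent of session mean."""

    power: np.ndarray  # channels x samples, >= 0
    fs: float
    names: list[str]
    bands: list[tuple[float, float]]

    @property
    def n_samples(self) -> int:
        return self.power.shape[1]


@dataclass
class EpochSet:
    """Baseline-corrected % power change, channels x trials x 64 samples.

    ``times`` is the in-epoch grid in seconds (k/64, k = -13..50);
    ``post`` slices the post-stimulus samples (t >= 0, 51 samples).
    """

    data: np.ndarray
    times: np.ndarray
    labels: np.ndarray  # trial_type per trial
    mask: TrialMask
    names: list[str]
    fs: float = FS_ENV

    @property
    def post(self) -> slice:
        return slice(int(np.searchsorted(self.times, 0.0)), len(self.times))

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.post]

    @property
    def prestim(self) -> slice:
        return slice(0, int(np.searchsorted(self.times, 0.0)))

    def trials_of(self, category: str, channel: int | None = None) -> np.ndarray:
        """Indices of usable trials of one category (on one channel if given)."""
        sel = self.labels == category
        if channel is not None:
            sel = sel & self.mask.usable[channel]
        return np.flatnonzero(sel)


def band_edges(low: float, high: float, width: float) -> list[tuple[float, float]]:
    """Contiguous non-overlapping bands covering [low, high]."""
    n = (high - low) / width
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"({low}, {high}) is not divisible into {width}-Hz bands")
    n = int(round(n))
    return [(low + i * width, low + (i + 1) * width) for i in range(n)]


def band_envelope(signal: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass, then Hilbert amplitude.

    Works on the last axis; accepts 1-D or channels x samples input.
    """
    low, high = band
    if high >= fs / 2:
        raise ValueError(f"band {band} at/above Nyquist ({fs / 2} Hz)")
    if low <= 0:
        raise ValueError("band low edge must be > 0")
    sos = butter(3, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, signal, axis=-1)
    n = filtered.shape[-1]
    nfft = next_fast_len(n)
    analytic = hilbert(filtered, N=nfft, axis=-1)[..., :n]
    return np.abs(analytic)


def bga_envelope(
    rec: BipolarRecording,
    low: float = 50.0,
    high: float = 150.0,
    width: float = 5.0,
    fs_env: float = FS_ENV,
) -> EnvelopeSeries:
    """Estimate the normalised BGA power series for every bipolar channel.

    Requires a 512 Hz recording at least 2 s long.  Per band: envelope at the
    recording rate, polyphase downsampling to ``fs_env``, division by the
    session mean (computed excluding ``EDGE_TRIM_S`` at both ends, where the
    zero-phase filter transients live); the normalised bands are averaged and
    scaled by 100.
    """
    if rec.fs != 512.0:
        raise ValueError(f"bga_envelope expects a 512 Hz recording, got {rec.fs}")
    if rec.duration < 2.0:
        raise ValueError("session shorter than filter warm-up (>= 2 s required)")
    factor = rec.fs / fs_env
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("fs must be an integer multiple of fs_env")
    bands = band_edges(low, high, width)
    acc: np.ndarray | None = None
    trim = None
    for band in bands:
        env = band_envelope(rec.signal, band, rec.fs)
        env64 = resample_poly(env, 1, int(round(factor)), axis=-1)
        # polyphase output can slightly undershoot zero near transients
        env64 = np.clip(env64, 0.0, None)
        if trim is None:
            n64 = env64.shape[-1]
            k = int(round(EDGE_TRIM_S * fs_env))
            trim = slice(k, n64 - k) if n64 > 2 * k else slice(0, n64)
        mean = env64[..., trim].mean(axis=-1, keepdims=True)
        acc = env64 / mean if acc is None else acc + env64 / mean
    power = 100.0 * acc / len(bands)
    return EnvelopeSeries(power=power, fs=fs_env, names=rec.names, bands=bands)


def epoch_envelope(
    env: EnvelopeSeries,
    events: pd.DataFrame,
    mask: TrialMask | None = None,
) -> EpochSet:
    """Epoch the BGA series around stimulus onsets and baseline-correct.

    Each event is mapped to the nearest 64 Hz sample; the epoch holds samples
    k = -13..50 relative to that sample and the mean over the [-50, 0) ms
    samples is subtracted.  Events too close to the recording edges are
    excluded with reason 'edge'.
    """
    n_ch = env.power.shape[0]
    n_tr = len(events)
    if mask is None:
        mask = TrialMask(
            usable=np.ones((n_ch, n_tr), bool), reason=np.full((n_ch, n_tr), "", object)
        )
    if mask.usable.shape != (n_ch, n_tr):
        raise ValueError("trial mask dimensions do not match envelope/events")
    ks = np.arange(EPOCH_K_MIN, EPOCH_K_MAX + 1)
    times = ks / env.fs
    data = np.zeros((n_ch, n_tr, ks.size))
    onsets = events["onset"].to_numpy(float)
    base_sel = (times >= BASELINE_WINDOW[0]) & (times < BASELINE_WINDOW[1])
    for t, onset in enumerate(onsets):
        n0 = int(round(onset * env.fs))
        i0, i1 = n0 + EPOCH_K_MIN, n0 + EPOCH_K_MAX
        if i0 < 0 or i1 >= env.n_samples:
            mask.exclude(slice(None), t, "edge")
            continue
        seg = env.power[:, i0 : i1 + 1]
        data[:, t, :] = seg - seg[:, base_sel].mean(axis=1, keepdims=True)
    return EpochSet(
        data=data,
        times=times,
        labels=events["trial_type"].to_numpy(object),
        mask=mask,
        names=list(env.names),
    )
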