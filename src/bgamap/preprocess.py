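"""Resampling, bipolar montage and trial exclusion.

Depth-electrode recordings are referenced to a distant contact, so each raw
contact picks up activity from widespread sources.  Subtracting adjacent
contacts on the same shaft (the *bipolar montage*) localises the signal to
the cortical volume between the two contacts; the analysis treats each
adjacent pair as one "channel", positioned at the pair midpoint in MNI space.

Trials are excluded per channel when an annotated interictal spike overlaps
the epoch window, and globally on keypress (behavioural-response) trials and
on trials whose epoch would exceed the recording bounds.
"""

from __future__ import annotations

from fractions import Fraction
from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .io_formats import Recording

__all__ = [
    "BipolarRecording",
    "TrialMask",
    "resample_recording",
    "bipolar_montage",
    "reject_trials",
]


@dataclass
class BipolarRecording:
    """Bipolar-derived recording: one row per adjacent contact pair.

    ``table`` columns: name (``A1-A2``), shaft, anode, cathode, x, y, z
    (pair midpoint, MNI mm), region, epileptic (true if either contact
    flagged), tissue (worst of the two contacts: heterotopic > white > gray).
    """

    signal: np.ndarray
    fs: float
    table: pd.DataFrame

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class TrialMask:
    """Per-channel trial usability with exclusion reasons.

    ``usable`` is channels x trials; ``reason`` holds '' | 'spike' |
    'keypress' | 'edge' (the first rule that excluded the trial; keypress and
    edge apply to all channels).
    """

    usable: np.ndarray
    reason: np.ndarray

    def exclude(self, ch: int | slice, tr: int | np.ndarray, why: str) -> None:
        sel = np.copy(self.usable[ch, tr])
        self.usable[ch, tr] = False
        # keep the first reason; only overwrite where previously usable
        prev = self.reason[ch, tr]
        self.reason[ch, tr] = np.where(sel, why, prev)

    @property
    def n_channels(self) -> int:
        return self.usable.shape[0]

    @property
    def n_trials(self) -> int:
        return self.usable.shape[1]


def resample_recording(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target_fs`` (downsampling only).

    A recording already at ``target_fs`` is returned unchanged (same object).
    """
    if target_fs > rec.fs:
        raise ValueError(f"upsampling {rec.fs} -> {target_fs} Hz is not supported")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    sig = resample_poly(rec.signal, frac.numerator, frac.denominator, axis=1)
    return Recording(signal=sig, fs=target_fs, channels=rec.channels, electrodes=rec.electrodes)


_TISSUE_RANK = {"gray": 0, "white": 1, "heterotopic": 2}


def bipolar_montage(rec: Recording) -> BipolarRecording:
    """Derive the bipolar montage: adjacent-contact differences per shaft.

    The difference is taken as deeper minus shallower contact (ascending
    contact index); a shaft with fewer than two contacts contributes no
    channels (warning).  Pair metadata: midpoint MNI, region of the deeper
    contact (joined with '|' if the two differ), epileptic if either contact
    is, tissue = worst of the pair.
    """
    if isinstance(rec, BipolarRecording):
        raise TypeError("recording is already bipolar; montage of a montage is invalid")
    meta = rec.channels.merge(rec.electrodes, on="name", suffixes=("", "_el"))
    if "shaft_el" in meta.columns:
        meta = meta.drop(columns=[c for c in meta.columns if c.endswith("_el")])
    rows = []
    sigs = []
    for shaft, grp in meta.groupby("shaft", sort=False):
        grp = grp.sort_values("contact")
        if len(grp) < 2:
            warnings.warn(f"shaft {shaft!r} has <2 contacts; no bipolar channels")
            continue
        idx = grp.index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            ra, rb = meta.loc[a], meta.loc[b]
            region = ra["region"] if ra["region"] == rb["region"] else f"{ra['region']}|{rb['region']}"
            tissue = max(ra["tissue"], rb["tissue"], key=_TISSUE_RANK.__getitem__)
            rows.append(
                {
                    "name": f"{ra['name']}-{rb['name']}",
                    "shaft": shaft,
                    "anode": ra["name"],
                    "cathode": rb["name"],
                    "x": (ra["x"] + rb["x"]) / 2,
                    "y": (ra["y"] + rb["y"]) / 2,
                    "z": (ra["z"] + rb["z"]) / 2,
                    "region": region,
                    "epileptic": bool(ra["epileptic"]) or bool(rb["epileptic"]),
                    "tissue": tissue,
                }
            )
            sigs.append(rec.signal[a] - rec.signal[b])
    if not rows:
        raise ValueError("no shaft yields a bipolar channel")
    return BipolarRecording(signal=np.vstack(sigs), fs=rec.fs, table=pd.DataFrame(rows))


def reject_trials(
    events: pd.DataFrame,
    annotations: pd.DataFrame,
    bipolar_table: pd.DataFrame,
    epoch_window: tuple[float, float] = (-0.2, 0.8),
    recording_duration: float | None = None,
) -> TrialMask:
    """Build the channel x trial usability mask.

    A trial is excluded on one channel when a spike annotation on that channel
    (matched by bipolar name or either constituent contact) overlaps the
    closed epoch interval ``[onset + w0, onset + w1]``; keypress trials and
    trials whose window exceeds the recording bounds are excluded on all
    channels.
    """
    n_ch = len(bipolar_table)
    n_tr = len(events)
    mask = TrialMask(
        usable=np.ones((n_ch, n_tr), bool), reason=np.full((n_ch, n_tr), "", object)
    )
    onsets = events["onset"].to_numpy(float)
    w0, w1 = epoch_window

    if recording_duration is not None:
        edge = (onsets + w0 < 0) | (onsets + w1 > recording_duration)
        for t in np.flatnonzero(edge):
            mask.exclude(slice(None), t, "edge")

    if "response" in events.columns:
        pressed = events["response"].to_numpy(bool)
        for t in np.flatnonzero(pressed):
            mask.exclude(slice(None), t, "keypress")

    if annotations is not None and len(annotations):
        name_to_idx: dict[str, list[int]] = {}
        for i, row in bipolar_table.reset_index(drop=True).iterrows():
            for key in (row["name"], row.get("anode"), row.get("cathode")):
                if key is not None:
                    name_to_idx.setdefault(key, []).append(i)
        for _, ann in annotations.iterrows():
            chans = name_to_idx.get(ann["channel"], [])
            if not chans:
                continue
            a0 = float(ann["onset"])
            a1 = a0 + float(ann["duration"])
            overlap = (onsets + w0 <= a1) & (onsets + w1 >= a0)
            for t in np.flatnonzero(overlap):
                for c in chans:
                    mask.exclude(c, t, "spike")
    return mask
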