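"""Recording container and sidecar table I/O.

Recordings are stored in a single hierarchical (HDF5) container holding the
signal matrix, the sampling rate and JSON-serialised channel/electrode
metadata; sidecar tables (channels, electrodes, events, annotations) follow
the BIDS-iEEG tab-separated dialect with a header row and ``n/a`` for missing
values.  Result tables are TSV, cluster reports JSON.  The container is
lossless (float64), so unit tests are not degraded by format quantisation.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "save_recording",
    "read_recording",
    "read_table",
    "write_table",
    "save_session",
    "load_session",
    "write_results",
    "read_results",
]

VALID_TISSUE = ("gray", "white", "heterotopic")

ELECTRODE_COLUMNS = ["name", "shaft", "contact", "x", "y", "z", "region", "epileptic", "tissue"]


@dataclass
class Recording:
    """A contact-level iEEG recording with its metadata tables.

    ``signal`` is channels x samples in volts; ``channels`` has one row per
    signal row (name, shaft, contact, status); ``electrodes`` carries MNI
    millimetre coordinates, region label, epileptic flag and tissue class.
    """

    signal: np.ndarray
    fs: float
    channels: pd.DataFrame
    electrodes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        self.signal = np.atleast_2d(np.asarray(self.signal, float))
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"channels table has {len(self.channels)} rows for "
                f"{self.signal.shape[0]} signal rows"
            )
        names = list(self.channels["name"])
        missing = [n for n in names if n not in set(self.electrodes["name"])]
        if missing:
            raise ValueError(f"electrodes table missing channels: {missing}")
        bad = self.electrodes.loc[~self.electrodes["tissue"].isin(VALID_TISSUE), "tissue"]
        if len(bad):
            raise ValueError(f"unknown tissue labels: {sorted(set(bad))}")
        coords = self.electrodes[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite MNI coordinates in electrodes table")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def electrode_row(self, name: str) -> pd.Series:
        return self.electrodes.set_index("name").loc[name]


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to the native HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.attrs["fs"] = rec.fs
        f.attrs["channels"] = rec.channels.to_json(orient="records")
        f.attrs["electrodes"] = rec.electrodes.to_json(orient="records")


def read_recording(path: str | Path) -> Recording:
    """Read a recording from the native container, validating metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        signal = f["signal"][()]
        fs = float(f.attrs["fs"])
        channels = pd.read_json(io.StringIO(f.attrs["channels"]), orient="records")
        electrodes = pd.read_json(io.StringIO(f.attrs["electrodes"]), orient="records")
    return Recording(signal=signal, fs=fs, channels=channels, electrodes=electrodes)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tab-separated table with 'n/a' for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=True)


def save_session(session, outdir: str | Path) -> Path:
    """Persist a simulated session: container + TSV sidecars + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_recording(session.recording, outdir / "recording.h5")
    write_table(session.events, outdir / "events.tsv")
    write_table(session.annotations, outdir / "annotations.tsv")
    write_table(session.recording.channels, outdir / "channels.tsv")
    write_table(session.recording.electrodes, outdir / "electrodes.tsv")
    (outdir / "ground_truth.json").write_text(
        json.dumps(session.ground_truth.to_dict(), indent=1, sort_keys=True)
    )
    return outdir


def load_session(indir: str | Path):
    """Load a session saved by :func:`save_session`."""
    from .simulate import GroundTruth, SimulatedSession

    indir = Path(indir)
    rec = read_recording(indir / "recording.h5")
    events = read_table(indir / "events.tsv")
    ann_path = indir / "annotations.tsv"
    try:
        annotations = read_table(ann_path)
    except pd.errors.EmptyDataError:
        annotations = pd.DataFrame(columns=["channel", "onset", "duration", "label"])
    if list(annotations.columns) != ["channel", "onset", "duration", "label"]:
        annotations = annotations.reindex(columns=["channel", "onset", "duration", "label"])
    gt_path = indir / "ground_truth.json"
    truth = GroundTruth.from_dict(json.loads(gt_path.read_text())) if gt_path.exists() else None
    return SimulatedSession(
        recording=rec, events=events, annotations=annotations, ground_truth=truth
    )


RESULT_COLUMNS = [
    "name",
    "x",
    "y",
    "z",
    "region",
    "tissue",
    "epileptic",
    "analyzable",
    "active_scene",
    "active_object",
    "class",
    "selectivity",
    "mixed",
    "magnitude_scene",
    "magnitude_object",
    "response_t90_scene",
    "response_t90_object",
    "late_scene",
    "late_object",
    "tsig",
    "lensig",
    "t90",
    "max_auc",
    "t_max_auc",
    "cluster",
    "excluded",
]


def write_results(results: pd.DataFrame, cluster_models: dict, outdir: str | Path) -> Path:
    """Write the per-channel results TSV and per-contrast cluster JSON reports.

    ``results`` must carry :data:`RESULT_COLUMNS`; rows are sorted by channel
    name for deterministic output.  ``cluster_models`` maps a contrast label
    (e.g. ``"scene"``) to a :class:`~bgamap.cluster.ClusterModel` or ``None``
    (no selective channels -> explicit "no clusters" report).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    out = results[RESULT_COLUMNS].sort_values("name", kind="stable").reset_index(drop=True)
    write_table(out, outdir / "results.tsv")
    for label, model in cluster_models.items():
        path = outdir / f"clusters_{label}.json"
        if model is None:
            report = {"k": 0, "clusters": [], "note": "no clusters: no selective channels"}
        else:
            report = model.report()
        path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return outdir


def read_results(outdir: str | Path) -> pd.DataFrame:
    return read_table(Path(outdir) / "results.tsv")
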