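"""End-to-end orchestration: recording -> per-channel results and reports.

The pipeline runs, in order: resampling to 512 Hz, bipolar montage, trial
exclusion (spike annotations, keypresses, edges), broadband-gamma envelope
estimation at 64 Hz, epoching, responsiveness detection per category,
scene-vs-object selectivity with timing measures, response magnitude, spatial
clustering of the scene- and object-selective channel sets, and per-channel
ROC time courses.  Channels in white matter or heterotopic cortex, and
channels whose response is still rising at the epoch end, are excluded from
the *active* set after detection (a filter, not a signal deletion); channels
flagged epileptic are kept by default, with their spike epochs excluded.

Everything is deterministic given the configuration seed: running the same
config twice produces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import ClusterModel, choose_k_stable
from .envelope import bga_envelope, epoch_envelope, EnvelopeSeries, EpochSet
from .io_formats import RESULT_COLUMNS, write_results, write_table
from .preprocess import bipolar_montage, reject_trials, resample_recording
from .roc import auc_timecourse
from .simulate import SimulatedSession
from .stats import assess_selectivity, bin_average, detect_responses, response_measures

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All fixed analysis constants in one place."""

    band_low: float = 50.0
    band_high: float = 150.0
    band_width: float = 5.0
    fs_signal: float = 512.0
    fs_env: float = 64.0
    epoch_window: tuple[float, float] = (-0.2, 0.8)
    q: float = 0.05
    sliding_window: int = 6
    min_trials: int = 10
    bin_width: float = 0.100
    contrast: tuple[str, str] = ("scene", "object")
    cluster_k_max: int = 8
    cluster_n_runs: int = 20
    seed: int = 0
    include_epileptic: bool = True
    exclude_tissue: bool = True  # drop white-matter/heterotopic channels from the active set
    exclude_late: bool = True  # drop channels still rising at the epoch end

    def __post_init__(self) -> None:
        if not (0 < self.q < 1):
            raise ValueError("q must be in (0, 1)")
        self.epoch_window = tuple(self.epoch_window)  # type: ignore[assignment]
        self.contrast = tuple(self.contrast)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epoch_window"] = list(self.epoch_window)
        d["contrast"] = list(self.contrast)
        return d


@dataclass
class RunReport:
    """Counts and summaries of one pipeline run (count identities hold)."""

    counts: dict
    clusters: dict
    config: dict
    version: str

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "clusters": self.clusters,
            "config": self.config,
            "version": self.version,
        }


def _float_or_nan(x) -> float:
    return float(x) if x is not None else float("nan")


def run_pipeline(
    session: SimulatedSession,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    envelope: EnvelopeSeries | None = None,
) -> tuple[RunReport, pd.DataFrame, dict, EpochSet]:
    """Run the full analysis on one session.

    Parameters
    ----------
    session
        Recording + events + spike annotations (a loaded directory or an
        in-memory simulation).
    envelope
        Optional precomputed :class:`EnvelopeSeries` to resume from; the
        downstream results are identical to a fresh computation.

    Returns ``(report, results_table, cluster_models, epochs)`` and, when
    ``outdir`` is given, writes ``results.tsv``, ``clusters_<cat>.json``,
    ``bin_means.tsv``, ``report.json`` and a manifest.
    """
    cfg = config or PipelineConfig()
    rec = resample_recording(session.recording, cfg.fs_signal)
    bip = bipolar_montage(rec)
    mask = reject_trials(
        session.events,
        session.annotations,
        bip.table,
        epoch_window=cfg.epoch_window,
        recording_duration=bip.duration,
    )
    if envelope is None:
        envelope = bga_envelope(bip, cfg.band_low, cfg.band_high, cfg.band_width, cfg.fs_env)
    epochs = epoch_envelope(envelope, session.events, mask)

    detection = detect_responses(
        epochs, cfg.contrast, q=cfg.q, window=cfg.sliding_window, min_trials=cfg.min_trials
    )
    selectivity = assess_selectivity(
        epochs, cfg.contrast, q=cfg.q, window=cfg.sliding_window, min_trials=cfg.min_trials
    )

    cat_a, cat_b = cfg.contrast
    n_ch = bip.n_channels
    rows = []
    for ch in range(n_ch):
        meta = bip.table.iloc[ch]
        row = {
            "name": meta["name"],
            "x": meta["x"],
            "y": meta["y"],
            "z": meta["z"],
            "region": meta["region"],
            "tissue": meta["tissue"],
            "epileptic": bool(meta["epileptic"]),
            "analyzable": bool(detection.analyzable[ch]),
            f"active_{cat_a}": bool(detection.active[cat_a][ch]),
            f"active_{cat_b}": bool(detection.active[cat_b][ch]),
            "class": detection.classes[ch],
            "selectivity": selectivity.direction[ch],
            "mixed": bool(selectivity.mixed[ch]),
            "tsig": selectivity.tsig[ch],
            "lensig": selectivity.lensig[ch],
            "t90": selectivity.t90[ch],
        }
        late_any = False
        for cat in cfg.contrast:
            if detection.active[cat][ch]:
                mag, rt90, late = response_measures(epochs, ch, cat)
            else:
                mag, rt90, late = float("nan"), float("nan"), False
            row[f"magnitude_{cat}"] = mag
            row[f"response_t90_{cat}"] = rt90
            row[f"late_{cat}"] = late
            late_any |= late
        excluded = []
        if not cfg.include_epileptic and row["epileptic"]:
            excluded.append("epileptic")
        if cfg.exclude_tissue and meta["tissue"] in ("white", "heterotopic"):
            excluded.append("tissue")
        if cfg.exclude_late and late_any:
            excluded.append("late")
        row["excluded"] = ";".join(excluded)
        rows.append(row)
    results = pd.DataFrame(rows)

    # active set = responding channels surviving the post-detection filters
    responding = detection.any_active
    kept = responding & (results["excluded"] == "").to_numpy()
    selective = selectivity.selective & kept

    # ROC time course for selective, kept channels
    results["max_auc"] = np.nan
    results["t_max_auc"] = np.nan
    for ch in np.flatnonzero(selective):
        prof = auc_timecourse(epochs, ch, selectivity.direction[ch], pair=cfg.contrast)
        results.loc[ch, "max_auc"] = prof.max_auc
        results.loc[ch, "t_max_auc"] = prof.max_time_ms

    # spatial clustering per selective set
    coords = results[["x", "y", "z"]].to_numpy(float)
    cluster_models: dict[str, ClusterModel | None] = {}
    results["cluster"] = ""
    for cat in cfg.contrast:
        sel = np.flatnonzero(selective & (selectivity.direction == cat))
        if sel.size < 2:
            cluster_models[cat] = None
            continue
        pts = coords[sel]
        model = choose_k_stable(
            pts,
            k_max=min(cfg.cluster_k_max, sel.size),
            n_runs=cfg.cluster_n_runs,
            seed=cfg.seed,
            hemispheres=np.where(pts[:, 0] < 0, "L", "R"),
            regions=results["region"].to_numpy(object)[sel],
            channel_names=list(results["name"].iloc[sel]),
        )
        cluster_models[cat] = model
        for i, ch in enumerate(sel):
            results.loc[ch, "cluster"] = f"{cat[0].upper()}{model.assignments[i] + 1}"

    classes_kept = results.loc[kept, "class"]
    counts = {
        "total_channels": int(n_ch),
        "analyzable": int(detection.analyzable.sum()),
        "responding": int(responding.sum()),
        "active": int(kept.sum()),
        "excluded_after_detection": int((responding & ~kept).sum()),
        "class_both": int((classes_kept == "both").sum()),
        f"class_{cat_a}_only": int((classes_kept == f"{cat_a}-only").sum()),
        f"class_{cat_b}_only": int((classes_kept == f"{cat_b}-only").sum()),
        f"selective_{cat_a}": int((selectivity.direction[selective] == cat_a).sum()),
        f"selective_{cat_b}": int((selectivity.direction[selective] == cat_b).sum()),
        "trials_total": int(epochs.mask.n_trials),
        "trials_excluded_keypress": int(
            (np.asarray(epochs.mask.reason[0]) == "keypress").sum()
        ),
        "per_region_active": {
            str(r): int(c)
            for r, c in results.loc[kept, "region"].value_counts().sort_index().items()
        },
    }
    report = RunReport(
        counts=counts,
        clusters={
            cat: (m.report() if m is not None else {"k": 0, "clusters": [], "note": "no clusters"})
            for cat, m in cluster_models.items()
        },
        config=cfg.to_dict(),
        version=__version__,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_results(results, cluster_models, outdir)
        means, edges = bin_average(epochs, cfg.contrast, cfg.bin_width)
        bin_rows = []
        for ch in range(n_ch):
            for ci, cat in enumerate(cfg.contrast):
                for b in range(means.shape[2]):
                    bin_rows.append(
                        {
                            "name": results["name"].iloc[ch],
                            "category": cat,
                            "bin_start_ms": int(round(edges[b] * 1000)),
                            "bin_end_ms": int(round(edges[b + 1] * 1000)),
                            "mean_power_change": means[ch, ci, b],
                        }
                    )
        write_table(pd.DataFrame(bin_rows), outdir / "bin_means.tsv")
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=1, sort_keys=True)
        )
        manifest = {
            "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
            "version": __version__,
            "seed": cfg.seed,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return report, results, cluster_models, epochs
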