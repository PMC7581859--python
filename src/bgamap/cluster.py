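"""Spatial clustering of category-selective channels in MNI space.

Selective channels are few, so left- and right-hemisphere channels are pooled
by folding the MNI x coordinate to its absolute value before clustering.
Channels are grouped by K-means with the city-block (L1) distance; with L1
distances the objective-minimising centroid is the coordinate-wise *median*,
which makes the procedure robust to stray channels.  The number of clusters
is chosen by silhouette analysis subject to a stability requirement: a
candidate k is accepted only when repeated runs from different seeded
initialisations (D^2 / k-means++-style seeding) all converge to the identical
partition; otherwise k is lowered (in order of decreasing silhouette) until a
stable solution is found.  The share of spatial variance a partition explains
is reported as the conventional sum-of-squares ratio (an L1 variant is
available as a switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples

__all__ = [
    "ClusterModel",
    "fold_coordinates",
    "kmeans_l1",
    "silhouette_l1",
    "choose_k_stable",
    "explained_variance",
]


def fold_coordinates(points: np.ndarray) -> np.ndarray:
    """Pool hemispheres: x <- |x|; y, z unchanged.  Idempotent."""
    pts = np.asarray(points, float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    out = pts.copy()
    out[..., 0] = np.abs(out[..., 0])
    return out


def _dsq_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++-style seeding with L1 distances (D^2 weighting).

    Each new centroid is chosen among ``2 + floor(log k)`` D^2-weighted
    candidates as the one minimising the resulting potential, which makes
    single-init runs on well-separated clusters converge reliably.
    """
    n = points.shape[0]
    n_trials = 2 + int(np.log(k)) if k > 1 else 1
    centroids = [points[rng.integers(n)]]
    d = cdist(points, centroids[-1][None], metric="cityblock").ravel()
    for _ in range(k - 1):
        w = d**2
        total = w.sum()
        if total == 0:
            centroids.append(points[rng.integers(n)])
            continue
        cand = rng.choice(n, size=n_trials, p=w / total)
        d_cand = np.minimum(d, cdist(points, points[cand], metric="cityblock").T)
        best = int(np.argmin((d_cand**2).sum(axis=1)))
        centroids.append(points[cand[best]])
        d = d_cand[best]
    return np.asarray(centroids, float)


def kmeans_l1(
    points: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd-style K-means under the city-block metric.

    Assignment: nearest centroid by L1 distance (ties to the lowest index);
    update: coordinate-wise median (mean of the two middle values for even
    cluster sizes); empty clusters are reseeded to the point farthest from
    its assigned centroid.  Returns ``(assignments, centroids, objective)``
    with the objective = sum of L1 distances to the assigned centroid,
    non-increasing across iterations.
    """
    points = np.atleast_2d(np.asarray(points, float))
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centroids = _dsq_init(points, k, rng)
    assign = np.full(n, -1)
    for _ in range(max_iter):
        d = cdist(points, centroids, metric="cityblock")
        new_assign = d.argmin(axis=1)
        for j in range(k):  # reseed empty clusters to the farthest point
            if not np.any(new_assign == j):
                far = d[np.arange(n), new_assign].argmax()
                new_assign[far] = j
                d[far] = -np.inf  # keep this point from seeding another empty cluster
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        centroids = np.array([np.median(points[assign == j], axis=0) for j in range(k)])
    objective = float(
        cdist(points, centroids, metric="cityblock")[np.arange(n), assign].sum()
    )
    return assign, centroids, objective


def silhouette_l1(points: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette with city-block dissimilarity (singletons score 0)."""
    points = np.atleast_2d(np.asarray(points, float))
    assignments = np.asarray(assignments)
    k = len(np.unique(assignments))
    if k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_samples(points, assignments, metric="cityblock").mean())


def explained_variance(
    points: np.ndarray, assignments: np.ndarray, metric: str = "l2"
) -> float:
    """Fraction of total spatial variance explained by a partition.

    ``l2`` (default): 1 - SS_within/SS_total with cluster means, the
    conventional sum-of-squares decomposition of spatial variance.  ``l1``:
    same ratio with L1 deviations from cluster medians.  Zero total variance
    is defined as fully explained (1).
    """
    points = np.atleast_2d(np.asarray(points, float))
    assignments = np.asarray(assignments)
    if metric == "l2":
        grand = points.mean(axis=0)
        total = ((points - grand) ** 2).sum()
        within = 0.0
        for j in np.unique(assignments):
            sub = points[assignments == j]
            within += ((sub - sub.mean(axis=0)) ** 2).sum()
    elif metric == "l1":
        grand = np.median(points, axis=0)
        total = np.abs(points - grand).sum()
        within = 0.0
        for j in np.unique(assignments):
            sub = points[assignments == j]
            within += np.abs(sub - np.median(sub, axis=0)).sum()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if total == 0:
        return 1.0
    return float(1.0 - within / total)


def _canonical(assign: np.ndarray) -> tuple:
    """Partition signature invariant to label permutation."""
    relabel: dict[int, int] = {}
    out = []
    for a in assign:
        if a not in relabel:
            relabel[a] = len(relabel)
        out.append(relabel[a])
    return tuple(out)


@dataclass
class ClusterModel:
    """A fitted spatial clustering of selective channels."""

    points: np.ndarray  # folded (|x|, y, z)
    k: int
    assignments: np.ndarray
    centroids: np.ndarray  # coordinate-wise medians
    silhouette: float
    explained: float  # fraction of spatial variance, L2 decomposition
    stable: bool
    n_runs: int
    match_fraction: float  # fraction of runs agreeing with the modal partition
    seed: int
    hemispheres: np.ndarray | None = None  # 'L'/'R' per point, pre-folding
    regions: np.ndarray | None = None
    channel_names: list[str] | None = None

    def report(self) -> dict:
        """JSON-serialisable cluster report: per-cluster N, L/R, composition, centroid."""
        clusters = []
        for j in range(self.k):
            sel = self.assignments == j
            sub = self.points[sel]
            entry: dict = {
                "cluster": j + 1,
                "n": int(sel.sum()),
                "centroid": {
                    "abs_x": [round(float(sub[:, 0].mean()), 1), round(float(sub[:, 0].std()), 1)],
                    "y": [round(float(sub[:, 1].mean()), 1), round(float(sub[:, 1].std()), 1)],
                    "z": [round(float(sub[:, 2].mean()), 1), round(float(sub[:, 2].std()), 1)],
                },
            }
            if self.hemispheres is not None:
                h = self.hemispheres[sel]
                entry["left_right"] = [int((h == "L").sum()), int((h == "R").sum())]
            if self.regions is not None:
                comp = pd.Series(self.regions[sel]).value_counts()
                entry["regions"] = {str(r): int(c) for r, c in comp.items()}
            if self.channel_names is not None:
                entry["channels"] = [self.channel_names[i] for i in np.flatnonzero(sel)]
            clusters.append(entry)
        return {
            "k": self.k,
            "n_points": int(self.points.shape[0]),
            "silhouette": round(self.silhouette, 4),
            "explained_variance": round(self.explained, 4),
            "stable": bool(self.stable),
            "n_runs": self.n_runs,
            "match_fraction": round(self.match_fraction, 4),
            "seed": self.seed,
            "clusters": clusters,
        }


def choose_k_stable(
    points: np.ndarray,
    k_max: int = 8,
    n_runs: int = 20,
    seed: int = 0,
    hemispheres: np.ndarray | None = None,
    regions: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> ClusterModel:
    """Select k by silhouette, subject to run-to-run stability.

    Every candidate k in 2..k_max is fit ``n_runs`` times from distinct
    seeded D^2 initialisations.  Candidates are ranked by the silhouette of
    their best-objective run; the highest-silhouette candidate whose runs all
    produce the identical partition (up to label permutation) wins.  If no
    candidate is stable, the k with the largest fraction of runs matching the
    modal partition is returned, flagged unstable.  Identical points (zero
    variance) collapse to a single stable cluster.
    """
    points = np.atleast_2d(np.asarray(points, float))
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    folded = fold_coordinates(points)

    def _model(k, assign, centroids, sil, stable, frac):
        return ClusterModel(
            points=folded,
            k=k,
            assignments=assign,
            centroids=centroids,
            silhouette=sil,
            explained=explained_variance(folded, assign),
            stable=stable,
            n_runs=n_runs,
            match_fraction=frac,
            seed=seed,
            hemispheres=hemispheres,
            regions=regions,
            channel_names=channel_names,
        )

    if np.ptp(folded, axis=0).max() == 0:  # all points identical
        return _model(1, np.zeros(n, int), folded[:1].copy(), 0.0, True, 1.0)

    k_max = min(k_max, n - 1)  # k = n has no silhouette (all singletons)
    if k_max < 2:  # two points: the only assessable partition is one cluster
        return _model(1, np.zeros(n, int), np.median(folded, axis=0)[None], 0.0, True, 1.0)
    ss = np.random.SeedSequence(seed)
    candidates = []
    for k in range(2, k_max + 1):
        rngs = [np.random.default_rng(s) for s in ss.spawn(n_runs)]
        runs = [kmeans_l1(folded, k, rng) for rng in rngs]
        partitions = [_canonical(a) for a, _, _ in runs]
        uniq: dict[tuple, int] = {}
        for p in partitions:
            uniq[p] = uniq.get(p, 0) + 1
        modal = max(uniq, key=uniq.get)
        frac = uniq[modal] / n_runs
        best = min(
            (r for r, p in zip(runs, partitions) if p == modal), key=lambda r: r[2]
        )
        sil = silhouette_l1(folded, best[0])
        candidates.append((k, best, sil, frac == 1.0, frac))
    candidates.sort(key=lambda c: -c[2])
    for k, (assign, centroids, _), sil, stable, frac in candidates:
        if stable:
            return _model(k, assign, centroids, sil, True, frac)
    k, (assign, centroids, _), sil, _, frac = max(candidates, key=lambda c: (c[4], c[2]))
    return _model(k, assign, centroids, sil, False, frac)
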