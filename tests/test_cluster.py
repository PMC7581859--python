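"""L1 k-means against a brute-force oracle; silhouette, variance, k selection."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from bgamap import (
    choose_k_stable,
    explained_variance,
    fold_coordinates,
    kmeans_l1,
    silhouette_l1,
)
from bgamap.simulate import plant_geometry


def brute_force_l1_objective(points, k):
    """Oracle: minimal sum of L1 distances to coordinate-wise cluster medians.

    Enumerates every assignment of n points to k non-empty clusters
    (feasible for n <= 7, k <= 3) and evaluates the optimal (median)
    centroid for each cluster.
    """
    points = np.atleast_2d(np.asarray(points, float))
    n = points.shape[0]
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) != k:
            continue
        assign = np.asarray(assign)
        obj = 0.0
        for j in range(k):
            sub = points[assign == j]
            obj += np.abs(sub - np.median(sub, axis=0)).sum()
        best = min(best, obj)
    return best


def best_of_restarts(points, k, n_restarts=10):
    runs = [kmeans_l1(points, k, seed=s) for s in range(n_restarts)]
    return min(runs, key=lambda r: r[2])


class TestKmeansL1:
    @pytest.mark.parametrize("n,k,seed", [(6, 2, 0), (7, 2, 1), (6, 3, 2), (7, 3, 3)])
    def test_reaches_brute_force_optimum(self, n, k, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 10, (n, 2))
        _, _, obj = best_of_restarts(pts, k)
        assert obj == pytest.approx(brute_force_l1_objective(pts, k), abs=1e-9)

    def test_two_pairs_objective_is_two(self):
        # {0,1} and {10,11}: median of each pair is the midpoint, each point
        # contributes 0.5, so the optimal objective is 2
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assign, centroids, obj = best_of_restarts(pts, 2)
        assert obj == pytest.approx(2.0, abs=1e-12)
        assert assign[0] == assign[1] and assign[2] == assign[3]
        assert sorted(centroids.ravel()) == pytest.approx([0.5, 10.5])

    def test_centroid_is_coordinatewise_median(self):
        # with an outlier the L1 centroid stays at the median, not the mean
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [100.0, 0.0]])
        _, centroids, _ = kmeans_l1(pts, 1, seed=0)
        assert centroids[0, 0] == pytest.approx(1.5)

    def test_k_one_objective_is_total_l1_deviation(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 5, (9, 3))
        _, _, obj = kmeans_l1(pts, 1, seed=0)
        assert obj == pytest.approx(np.abs(pts - np.median(pts, axis=0)).sum())

    def test_determinism(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 5, (12, 3))
        a1, c1, o1 = kmeans_l1(pts, 3, seed=11)
        a2, c2, o2 = kmeans_l1(pts, 3, seed=11)
        assert np.array_equal(a1, a2) and np.array_equal(c1, c2) and o1 == o2

    def test_k_out_of_range_rejected(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError):
            kmeans_l1(pts, 4)
        with pytest.raises(ValueError):
            kmeans_l1(pts, 0)


class TestSilhouette:
    def test_hand_computed_four_point_value(self):
        # points 0,1 | 10,11: s(0) = (10.5-1)/10.5, s(1) = (9.5-1)/9.5,
        # symmetric for the other pair -> mean = (9.5/10.5 + 8.5/9.5)/2
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assign = np.array([0, 0, 1, 1])
        expected = (9.5 / 10.5 + 8.5 / 9.5) / 2
        assert silhouette_l1(pts, assign) == pytest.approx(expected, abs=1e-12)

    def test_tight_well_separated_clusters_near_one(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(50, 0.1, (20, 3))])
        assign = np.repeat([0, 1], 20)
        assert silhouette_l1(pts, assign) > 0.95

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_l1(np.zeros((4, 2)), np.zeros(4, int))


class TestExplainedVariance:
    def test_singleton_clusters_explain_everything(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 5, (6, 3))
        assert explained_variance(pts, np.arange(6)) == pytest.approx(1.0)

    def test_one_cluster_explains_nothing(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 5, (6, 3))
        assert explained_variance(pts, np.zeros(6, int)) == pytest.approx(0.0, abs=1e-12)

    def test_four_point_hand_computation(self):
        # SS_within = 4 * 0.25 = 1; SS_total about the grand mean 5.5 is
        # 30.25 + 20.25 + 20.25 + 30.25 = 101 -> 1 - 1/101
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assign = np.array([0, 0, 1, 1])
        assert explained_variance(pts, assign) == pytest.approx(1 - 1 / 101, abs=1e-12)

    def test_l1_variant_four_points(self):
        # L1: within = 4 * 0.5 = 2; total about the grand median 5.5 is
        # 5.5 + 4.5 + 4.5 + 5.5 = 20
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        assign = np.array([0, 0, 1, 1])
        assert explained_variance(pts, assign, metric="l1") == pytest.approx(1 - 2 / 20)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            explained_variance(np.zeros((4, 2)), np.zeros(4, int), metric="l3")


class TestFoldCoordinates:
    def test_x_folded_y_z_kept(self):
        pts = np.array([[-30.0, -45.0, -7.0], [30.0, -45.0, -7.0]])
        out = fold_coordinates(pts)
        assert np.allclose(out[0], [30.0, -45.0, -7.0])
        assert np.allclose(out[0], out[1])

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 40, (10, 3))
        once = fold_coordinates(pts)
        assert np.allclose(fold_coordinates(once), once)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fold_coordinates(np.array([[np.nan, 0.0, 0.0]]))


class TestChooseKStable:
    def test_recovers_three_planted_clusters(self):
        centroids = [(30.0, -45.0, -7.0), (38.0, -76.0, 24.0), (16.0, -53.0, 12.0)]
        coords, labels = plant_geometry(centroids, n_per_cluster=15, spread_mm=4.0, seed=10)
        model = choose_k_stable(coords, k_max=6, n_runs=20, seed=0)
        assert model.k == 3
        assert model.stable
        assert adjusted_rand_score(labels, model.assignments) >= 0.9
        assert model.explained > 0.8

    def test_identical_points_single_stable_cluster(self):
        pts = np.tile([10.0, 20.0, 30.0], (5, 1))
        model = choose_k_stable(pts)
        assert model.k == 1 and model.stable and model.match_fraction == 1.0

    def test_hemisphere_folding_pools_mirror_clusters(self):
        # mirrored left/right sites form one folded cluster, not two
        rng = np.random.default_rng(11)
        right = rng.normal([35.0, -50.0, 0.0], 2.0, (8, 3))
        left = right * np.array([-1.0, 1.0, 1.0])
        far = rng.normal([10.0, 40.0, 40.0], 2.0, (8, 3))
        model = choose_k_stable(np.vstack([right, left, far]), k_max=5, seed=1)
        assert model.k == 2
        same = model.assignments[:8]
        assert np.array_equal(same, model.assignments[8:16])

    def test_report_structure_and_counts(self):
        centroids = [(30.0, -45.0, -7.0), (38.0, -76.0, 24.0)]
        coords, _ = plant_geometry(centroids, n_per_cluster=6, spread_mm=3.0, seed=12)
        hemis = np.array(["R"] * 12, object)
        names = [f"A{i}-A{i + 1}" for i in range(12)]
        model = choose_k_stable(
            coords, k_max=4, seed=2, hemispheres=hemis,
            regions=np.array(["phlg"] * 12, object), channel_names=names,
        )
        rep = model.report()
        assert rep["k"] == model.k
        assert sum(c["n"] for c in rep["clusters"]) == 12
        assert sorted(ch for c in rep["clusters"] for ch in c["channels"]) == sorted(names)

    def test_determinism(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(0, 20, (15, 3))
        m1 = choose_k_stable(pts, seed=3)
        m2 = choose_k_stable(pts, seed=3)
        assert m1.k == m2.k
        assert np.array_equal(m1.assignments, m2.assignments)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            choose_k_stable(np.zeros((1, 3)))
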