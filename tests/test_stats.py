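"""Rank-sum oracle, sliding window, FDR, detection/selectivity, timing, bins."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bgamap import (
    assess_selectivity,
    bin_average,
    detect_responses,
    discrimination_timing,
    fdr_select,
    ranksum_p,
    response_measures,
    sliding_max_p,
)
from bgamap.envelope import FS_ENV

from conftest import make_epochs


def exact_ranksum_p(x, y):
    """Enumeration oracle: two-sided p of the rank-sum statistic.

    Enumerates all C(n+m, n) assignments of the pooled (tie-free) values to
    group x and counts arrangements with |U - mu| >= observed.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    nx, ny = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    mu = nx * ny / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(1, nx + ny + 1), nx):
        u = sum(comb) - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestRanksum:
    def test_separated_triplets_exact_p(self):
        assert ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_constant_samples_give_one(self):
        assert ranksum_p([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_strong_separation_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        y = rng.normal(3, 1, 50)
        assert ranksum_p(x, y) < 1e-6

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            ranksum_p([1.0], [2.0, 3.0])

    @given(
        nx=st.integers(2, 6),
        ny=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0.8, 1, ny)
        assert ranksum_p(x, y) == pytest.approx(exact_ranksum_p(x, y), abs=0.01)


class TestSlidingMaxP:
    def test_constant_series_unchanged(self):
        p = np.full(20, 0.03)
        assert np.allclose(sliding_max_p(p, 6), 0.03)

    def test_isolated_low_p_removed(self):
        p = np.full(12, 0.5)
        p[4] = 0.001
        assert np.allclose(sliding_max_p(p, 6), 0.5)

    def test_window_evaluation_at_series_end(self):
        p = np.array([0.01] * 6 + [0.5] * 4)
        adj = sliding_max_p(p, 6)
        assert adj[0] == pytest.approx(0.01)
        assert adj[1] == pytest.approx(0.5)
        assert adj[-1] == pytest.approx(0.5)

    def test_oversized_window_truncates_to_suffix_max(self):
        p = np.array([0.2, 0.7, 0.1])
        assert np.allclose(sliding_max_p(p, 10), [0.7, 0.7, 0.1])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random((3, 40))
        assert (sliding_max_p(p, 6) >= p).all()


class TestFdrSelect:
    def test_step_up_rescues_later_p(self):
        # largest k with p_(k) <= k q / m is k = 4 -> all four selected
        sel = fdr_select(np.array([0.001, 0.008, 0.039, 0.041]), q=0.05)
        assert sel.all()

    def test_all_large_p_nothing_selected(self):
        assert not fdr_select(np.full(10, 0.9), q=0.05).any()

    def test_single_boundary_p_selected(self):
        assert fdr_select(np.array([0.05]), q=0.05).all()

    def test_empty_input(self):
        assert fdr_select(np.empty((0, 5))).size == 0

    def test_shape_preserved(self):
        rng = np.random.default_rng(2)
        p = rng.random((4, 7))
        assert fdr_select(p).shape == (4, 7)

    def test_lowering_q_never_adds_detections(self):
        rng = np.random.default_rng(3)
        p = rng.random(200) ** 2
        loose = fdr_select(p, q=0.05)
        tight = fdr_select(p, q=0.01)
        assert not np.any(tight & ~loose)


def _epochs_with_effect(
    n_ch=4,
    n_tr=40,
    scene_gain=40.0,
    object_gain=0.0,
    onset_s=0.2,
    dur_s=0.3,
    noise=8.0,
    seed=0,
    effect_channels=None,
):
    """Synthetic EpochSet straight at the epoch level (fast statistics tests)."""
    rng = np.random.default_rng(seed)
    labels = np.array(["scene", "object"] * (n_tr // 2), object)
    times = np.arange(-13, 51) / FS_ENV
    data = rng.normal(0, noise, (n_ch, n_tr, 64))
    if effect_channels is None:
        effect_channels = range(n_ch // 2)
    pulse = ((times >= onset_s) & (times < onset_s + dur_s)).astype(float)
    for ch in effect_channels:
        data[ch, labels == "scene"] += scene_gain * pulse
        data[ch, labels == "object"] += object_gain * pulse
    return make_epochs(data, labels)


class TestDetectResponses:
    def test_planted_channels_detected_nulls_not(self):
        ep = _epochs_with_effect(n_ch=6, scene_gain=40.0, seed=1)
        det = detect_responses(ep)
        assert det.active["scene"][:3].all()
        assert not det.active["scene"][3:].any()
        assert not det.active["object"][3:].any()

    def test_class_labels(self):
        ep = _epochs_with_effect(n_ch=2, scene_gain=40.0, object_gain=40.0, seed=2,
                                 effect_channels=[0])
        det = detect_responses(ep)
        assert det.classes[0] == "both"
        assert det.classes[1] == "none"

    def test_too_few_trials_marks_not_analyzable(self):
        ep = _epochs_with_effect(n_ch=2, n_tr=10, seed=3)  # 5 trials per category
        det = detect_responses(ep)
        assert not det.analyzable.any()
        assert not det.active["scene"].any()


class TestAssessSelectivity:
    def test_scene_selective_channel_found(self):
        ep = _epochs_with_effect(scene_gain=40.0, object_gain=10.0, seed=4)
        sel = assess_selectivity(ep)
        assert (sel.direction[:2] == "scene").all()
        assert (sel.direction[2:] == "none").all()

    def test_label_swap_flips_direction(self):
        ep = _epochs_with_effect(scene_gain=40.0, object_gain=10.0, seed=5)
        a = assess_selectivity(ep, pair=("scene", "object"))
        b = assess_selectivity(ep, pair=("object", "scene"))
        assert (a.map.raw_p == b.map.raw_p).all()
        # the winning category is the same whichever way the pair is written;
        # the signed difference series flips with the pair order
        assert (a.direction == b.direction).all()
        assert np.allclose(a.difference, -b.difference)
        assert np.allclose(a.tsig, b.tsig, equal_nan=True)

    def test_timing_measures_populated_only_when_selective(self):
        ep = _epochs_with_effect(scene_gain=40.0, object_gain=0.0, onset_s=0.2, seed=6)
        sel = assess_selectivity(ep)
        assert np.isfinite(sel.tsig[:2]).all()
        assert np.isnan(sel.tsig[2:]).all()
        # recovered discrimination onset near the planted 200 ms
        assert np.abs(sel.tsig[:2] - 200.0).max() <= 47.0


class TestDiscriminationTiming:
    def test_first_significant_sample_index_10(self):
        sig = np.zeros(51, bool)
        sig[10:29] = True
        diff = np.linspace(0, 1, 51)
        tsig, lensig, _ = discrimination_timing(sig, diff)
        assert tsig == pytest.approx(156.25)
        assert lensig == pytest.approx(19 * 15.625)  # 296.875 ms

    def test_t90_of_linear_ramp(self):
        # ramp reaching its max at sample 40 (625 ms): 90% first reached at
        # sample 36 (562.5 ms) on the 64 Hz grid
        diff = np.concatenate([np.linspace(0, 1, 41), np.full(10, 0.0)])
        sig = np.ones(51, bool)
        _, _, t90 = discrimination_timing(sig, diff)
        assert t90 == pytest.approx(36 / 64 * 1000)

    def test_no_significance_reported_missing(self):
        tsig, lensig, t90 = discrimination_timing(np.zeros(51, bool), np.full(51, -1.0))
        assert math.isnan(tsig) and math.isnan(lensig) and math.isnan(t90)


class TestResponseMeasures:
    def test_magnitude_is_peak_of_trial_mean(self):
        ep = _epochs_with_effect(n_ch=1, scene_gain=42.0, noise=0.01, seed=7,
                                 effect_channels=[0])
        mag, t90, late = response_measures(ep, 0, "scene")
        assert mag == pytest.approx(42.0, abs=0.5)
        assert 150.0 <= t90 <= 250.0
        assert not late

    def test_all_negative_mean_gives_zero_magnitude(self):
        data = np.full((1, 20, 64), -5.0)
        ep = make_epochs(data, np.array(["scene", "object"] * 10, object))
        mag, t90, late = response_measures(ep, 0, "scene")
        assert mag == 0.0
        assert math.isnan(t90)

    def test_ramp_peaking_at_epoch_end_is_late(self):
        times = np.arange(-13, 51) / FS_ENV
        data = np.tile(np.maximum(times, 0) * 50, (1, 20, 1))
        ep = make_epochs(data, np.array(["scene", "object"] * 10, object))
        _, _, late = response_measures(ep, 0, "scene")
        assert late


class TestBinAverage:
    def test_constant_response_constant_bins(self):
        data = np.full((1, 20, 64), 10.0)
        ep = make_epochs(data, np.array(["scene", "object"] * 10, object))
        means, edges = bin_average(ep)
        assert means.shape == (1, 2, 8)
        assert np.allclose(means, 10.0)
        assert np.allclose(edges, np.arange(9) * 0.1)

    def test_linear_ramp_bin_means_match_sample_average_oracle(self):
        times = np.arange(-13, 51) / FS_ENV
        ramp = times * 64.0
        data = np.tile(ramp, (1, 20, 1))
        ep = make_epochs(data, np.array(["scene"] * 20, object))
        means, _ = bin_average(ep, categories=("scene",))
        post_t = times[13:]
        expected = [64.0 * post_t[(post_t >= b * 0.1) & (post_t < (b + 1) * 0.1)].mean()
                    for b in range(8)]
        assert np.allclose(means[0, 0], expected)

    def test_non_divisible_width_rejected(self):
        data = np.zeros((1, 4, 64))
        ep = make_epochs(data, np.array(["scene"] * 4, object))
        with pytest.raises(ValueError, match="divide"):
            bin_average(ep, bin_width=0.15)
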