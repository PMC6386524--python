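"""The smoothed-maximum statistic, thresholding, regions, and the permutation test."""

import numpy as np
import pytest

from mgcorr import (
    SimulationSpec,
    compute_threshold,
    largest_significant_region,
    mgc_statistic_from_distances,
    mgc_test,
    pairwise_distances,
    permutation_test,
    sample_relationship,
)


class TestThreshold:
    def test_global_correlation_dominates_when_large(self):
        C = np.full((50, 50), 0.005)
        C[-1, -1] = 0.2
        # no negatives: variance term is 0, floor gives 0.035; 2/n = 0.04
        assert compute_threshold(C) == pytest.approx(0.2)

    def test_noise_floor_when_negatives_are_small(self):
        C = np.zeros((100, 100))
        C[10:20, 10:20] = -0.05  # mean squared negative = 0.0025 < 0.01 floor
        C[-1, -1] = 0.0
        assert compute_threshold(C) == pytest.approx(0.035)

    def test_negative_variance_term_scales_threshold(self):
        C = np.zeros((100, 100))
        C[0, 1] = -0.3
        C[1, 0] = -0.1
        var_neg = (0.09 + 0.01) / 2
        assert compute_threshold(C) == pytest.approx(3.5 * var_neg)

    def test_never_below_global_correlation(self, rng):
        for _ in range(10):
            C = rng.uniform(-1, 1, (12, 12))
            assert compute_threshold(C) >= C[-1, -1]


class TestSignificantRegion:
    def test_nothing_significant(self):
        region = largest_significant_region(np.zeros((6, 6)), 0.1)
        assert region.size == 0 and not region.mask.any()

    def test_picks_larger_of_two_blocks(self):
        C = np.zeros((10, 10))
        C[0:1, 0:5] = 1.0  # 5 scales
        C[5:8, 5:8] = 1.0  # 9 scales, disconnected from the strip
        region = largest_significant_region(C, 0.5)
        assert region.size == 9
        assert region.mask[5:8, 5:8].all() and not region.mask[0, 0]

    def test_fully_significant_map(self):
        region = largest_significant_region(np.ones((7, 7)), 0.5)
        assert region.size == 49

    def test_diagonal_touch_is_connected(self):
        # 8-connectivity joins diagonally adjacent scales
        C = np.zeros((6, 6))
        C[0, 0] = C[1, 1] = C[2, 2] = 1.0
        region = largest_significant_region(C, 0.5)
        assert region.size == 3


class TestMgcStatistic:
    def test_affine_pair_statistic_one_global_scale(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (20, 1))
        Y = 2 * X + 3
        c, scales, C, _ = mgc_statistic_from_distances(
            pairwise_distances(X), pairwise_distances(Y), scheme="unbiased")
        assert c == pytest.approx(1.0, abs=1e-10)
        assert scales == [(20, 20)]

    def test_small_region_defaults_to_global(self, rng):
        # independent data: the significant region is (almost surely) tiny
        X = rng.standard_normal((30, 1))
        Y = rng.standard_normal((30, 1))
        c, scales, C, region = mgc_statistic_from_distances(
            pairwise_distances(X), pairwise_distances(Y))
        if region.size < 2 * 30:
            assert c == pytest.approx(C[-1, -1], abs=0)
            assert scales == [(30, 30)]

    @pytest.mark.parametrize("scheme,min_local", [("single_column", 90), ("unbiased", 75)])
    def test_spiral_prefers_local_scale(self, scheme, min_local):
        # strongly nonlinear dependence: the optimal scale is usually non-global.
        # Single centering localizes most aggressively (93/100 on this seed
        # ladder); U-centering is more conservative (79/100). Bounds frozen
        # from those Monte-Carlo counts with a small cross-platform margin.
        local = 0
        for seed in range(100):
            pair = sample_relationship(SimulationSpec(8, n=60, p=1, kappa=1, seed=seed))
            _, scales, _, _ = mgc_statistic_from_distances(
                pairwise_distances(pair.X), pairwise_distances(pair.Y), scheme=scheme)
            local += scales[0] != (60, 60)
        assert local >= min_local

    def test_optimal_scales_attain_statistic(self):
        pair = sample_relationship(SimulationSpec(8, n=50, p=1, kappa=1, seed=3))
        c, scales, C, _ = mgc_statistic_from_distances(
            pairwise_distances(pair.X), pairwise_distances(pair.Y))
        for k, l in scales:
            assert C[k - 1, l - 1] == pytest.approx(c, abs=1e-12)


class TestPermutationTest:
    def test_p_value_bounds(self, rng):
        X = rng.standard_normal((12, 1))
        Y = rng.standard_normal((12, 1))
        p = permutation_test(pairwise_distances(X), pairwise_distances(Y), r=19, seed=0)
        assert 1 / 20 <= p <= 1.0

    def test_noiseless_linear_reaches_minimum_p(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(-1, 1, (30, 1))
        Y = 3 * X - 1
        p = permutation_test(pairwise_distances(X), pairwise_distances(Y), r=999, seed=4)
        assert p == pytest.approx(1 / 1000)

    def test_requires_at_least_one_permutation(self, rng):
        X = rng.standard_normal((8, 1))
        D = pairwise_distances(X)
        with pytest.raises(ValueError):
            permutation_test(D, D, r=0, seed=0)


class TestMgcTest:
    def test_deterministic_given_seed(self):
        pair = sample_relationship(SimulationSpec(6, n=25, p=1, kappa=1, seed=9))
        r1 = mgc_test(pair.X, pair.Y, n_permutations=50, seed=123)
        r2 = mgc_test(pair.X, pair.Y, n_permutations=50, seed=123)
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value
        assert r1.optimal_scales == r2.optimal_scales
        assert np.array_equal(r1.map, r2.map)

    def test_constant_y_degenerates_to_null(self, rng):
        X = rng.standard_normal((15, 1))
        Y = np.full((15, 1), 2.0)
        res = mgc_test(X, Y, n_permutations=20, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_noisy_linear_rejects(self):
        pair = sample_relationship(SimulationSpec(1, n=50, p=1, kappa=0, seed=2))
        res = mgc_test(pair.X, pair.Y, n_permutations=999, seed=7)
        assert res.p_value < 0.05

    def test_mismatched_sample_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="same number"):
            mgc_test(rng.standard_normal((10, 1)), rng.standard_normal((11, 1)),
                     n_permutations=10)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            mgc_test(rng.standard_normal((3, 1)), rng.standard_normal((3, 1)),
                     n_permutations=10)

    def test_isometry_and_scaling_leave_result_unchanged(self):
        pair = sample_relationship(SimulationSpec(6, n=30, p=2, kappa=1, seed=21))
        X, Y = pair.X, pair.Y
        base = mgc_test(X, Y, n_permutations=100, seed=5)
        Q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((2, 2)))
        for Xt in (X + 7.5, X @ Q, -X, 3.25 * X):
            res = mgc_test(Xt, Y, n_permutations=100, seed=5)
            assert res.statistic == pytest.approx(base.statistic, abs=1e-10)
            assert res.p_value == base.p_value
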