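import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pairstat as ps
from conftest import obs


class TestRankWithTies:
    @pytest.mark.parametrize("values,expected", [
        ([10, 20, 20, 30], [1, 2.5, 2.5, 4]),
        ([1, 2, 3, 4], [1, 2, 3, 4]),
        ([5, 5, 5], [2, 2, 2]),
        ([3, 1, 2], [3, 1, 2]),
    ])
    def test_examples(self, values, expected):
        np.testing.assert_array_equal(ps.rank_with_ties(values), expected)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=40))
    def test_rank_sum_invariant(self, vals):
        n = len(vals)
        assert ps.rank_with_ties(vals).sum() == pytest.approx(n * (n + 1) / 2)


class TestPearsonPair:
    def test_perfect_correlation(self):
        res = ps.pearson_pair(obs([0, 1, 2], [0, 1, 2]))
        assert res.statistic == 1.0
        assert res.effects["r2"] == 1.0
        assert res.p_value == 0.0

    def test_single_observation_all_nan(self):
        res = ps.pearson_pair(obs([1.0], [2.0]))
        assert math.isnan(res.statistic) and math.isnan(res.p_value)
        assert math.isnan(res.effects["r2"])

    def test_two_observations_r_defined_p_undefined(self):
        res = ps.pearson_pair(obs([0, 1], [3, 1]))
        assert res.statistic == -1.0
        assert math.isnan(res.p_value)

    def test_zero_variance_nan(self):
        res = ps.pearson_pair(obs([1, 1, 1], [1, 2, 3]))
        assert math.isnan(res.statistic) and math.isnan(res.p_value)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 30))
        res = ps.pearson_pair(obs(x, y))
        r, p = stats.pearsonr(x, y)
        assert res.statistic == pytest.approx(r, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_p_monotone_in_abs_r_at_fixed_n(self):
        from pairstat.correlation import pearson_p
        grid = np.arange(-0.9, 0.95, 0.1)
        ps_vals = [pearson_p(r, 10) for r in grid]
        for r, p in zip(grid, ps_vals):
            ab = 4.0  # n/2 - 1 at n = 10
            ref = 2 * stats.beta.cdf(-abs(r), ab, ab, loc=-1, scale=2)
            assert p == pytest.approx(ref, rel=1e-12)
        order = np.argsort(np.abs(grid))
        assert all(np.diff(np.array(ps_vals)[order]) <= 1e-12)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=(2, 25))
        base = ps.pearson_pair(obs(x, y))
        scaled = ps.pearson_pair(obs(3.0 * x + 7.0, 0.5 * y - 2.0))
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-12)


class TestSpearmanPair:
    def test_perfect_anticorrelation(self):
        res = ps.spearman_pair(obs([1, 2, 3, 4], [4, 3, 2, 1]))
        assert res.statistic == -1.0
        assert res.p_value == 0.0

    def test_two_observations_p_undefined(self):
        res = ps.spearman_pair(obs([1, 2], [5, 9]))
        assert abs(res.statistic) == 1.0
        assert math.isnan(res.p_value)

    def test_single_observation_all_nan(self):
        res = ps.spearman_pair(obs([1.0], [1.0]))
        assert math.isnan(res.statistic) and math.isnan(res.p_value)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.uniform(0, 1, 25), 1)  # heavy ties
        y = rng.uniform(0, 1, 25)
        res = ps.spearman_pair(obs(x, y))
        rho, p = stats.spearmanr(x, y)
        assert res.statistic == pytest.approx(rho, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.uniform(1, 2, size=(2, 30))
        base = ps.spearman_pair(obs(x, y))
        warped = ps.spearman_pair(obs(np.exp(x), y ** 3))
        assert warped.statistic == pytest.approx(base.statistic, rel=1e-12)
        assert warped.p_value == pytest.approx(base.p_value, rel=1e-12)
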