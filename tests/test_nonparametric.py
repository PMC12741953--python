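import math

import numpy as np
import pytest
from scipy import stats

import pairstat as ps
from conftest import grouped
from oracles import mwu_enumerated


class TestExactUDistribution:
    def test_minimal_case(self):
        dist = ps.mwu_exact_distribution(1, 1)
        assert dist.freq == [1, 1]

    def test_two_by_two(self):
        dist = ps.mwu_exact_distribution(2, 2)
        assert dist.freq == [1, 1, 2, 1, 1]
        assert dist.total == 6

    @pytest.mark.parametrize("n1,n2", [(1, 3), (2, 3), (3, 3), (2, 5), (4, 4)])
    def test_matches_enumeration(self, n1, n2):
        dist = ps.mwu_exact_distribution(n1, n2)
        assert dist.freq == mwu_enumerated(n1, n2)

    def test_symmetry_and_total(self):
        dist = ps.mwu_exact_distribution(3, 5)
        assert dist.freq == dist.freq[::-1]
        assert dist.total == math.comb(8, 3)

    def test_size_bound_advises_asymptotic(self):
        with pytest.raises(ValueError, match="asymptotic"):
            ps.mwu_exact_distribution(3000, 3000)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            ps.mwu_exact_distribution(0, 4)


class TestMwuPair:
    def test_exact_example(self):
        res = ps.mwu_pair(grouped([[1, 2], [3, 4]]), mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3, rel=1e-15)

    def test_empty_group_all_nan(self):
        res = ps.mwu_pair(grouped([[], [1, 2, 3]]))
        assert math.isnan(res.statistic) and math.isnan(res.p_value)

    def test_exact_mode_with_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            ps.mwu_pair(grouped([[1, 1, 2], [2, 3, 4]]), mode="exact")

    def test_u1_u2_sum_and_two_sided_symmetry(self, rng):
        a, b = rng.uniform(size=(2, 6))
        r1 = ps.mwu_pair(grouped([a, b]), mode="exact")
        r2 = ps.mwu_pair(grouped([b, a]), mode="exact")
        assert r1.statistic + r2.statistic == 36
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-15)

    @pytest.mark.parametrize("seed", range(4))
    def test_auto_matches_scipy_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, 6)
        b = rng.uniform(0.2, 1.2, 7)
        res = ps.mwu_pair(grouped([a, b]), mode="auto")
        u, p = stats.mannwhitneyu(a, b, method="auto")
        assert res.statistic == u
        assert res.p_value == pytest.approx(p, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_asymptotic_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.uniform(0, 1, 20), 1)
        b = np.round(rng.uniform(0.1, 1.1, 25), 1)
        res = ps.mwu_pair(grouped([a, b]), mode="asymptotic")
        u, p = stats.mannwhitneyu(a, b, method="asymptotic")
        assert res.statistic == u
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_effect_size_is_z_over_sqrt_n(self, rng):
        a, b = rng.uniform(size=(2, 30))
        res = ps.mwu_pair(grouped([a, b]), mode="asymptotic")
        assert 0.0 <= res.effects["pearson_r"] <= 1.0

    def test_exact_asymptotic_convergence_at_n20(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            a, b = rng.uniform(size=(2, 20))
            pe = ps.mwu_pair(grouped([a, b]), mode="exact").p_value
            pa = ps.mwu_pair(grouped([a, b]), mode="asymptotic").p_value
            assert abs(pe - pa) < 0.01

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.uniform(1, 2, size=(2, 12))
        base = ps.mwu_pair(grouped([a, b]))
        warped = ps.mwu_pair(grouped([np.log(a), np.log(b)]))
        assert warped.statistic == base.statistic
        assert warped.p_value == pytest.approx(base.p_value, rel=1e-12)


class TestKruskalPair:
    def test_identical_rank_distributions(self):
        res = ps.kruskal_pair(grouped([[1, 2, 3], [1, 2, 3]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_eta2_undefined_when_n_equals_k(self):
        res = ps.kruskal_pair(grouped([[1], [2], [3]]))
        assert math.isnan(res.effects["eta2"])
        assert not math.isnan(res.statistic)

    def test_all_values_tied_nan(self):
        res = ps.kruskal_pair(grouped([[1, 1], [1, 1]]))
        assert math.isnan(res.statistic) and math.isnan(res.p_value)

    def test_lost_category_all_nan(self):
        res = ps.kruskal_pair(grouped([[1, 2], [3, 4]], expected=3))
        assert math.isnan(res.statistic)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [np.round(rng.uniform(0, 1, 15), 1) for _ in range(3)]
        res = ps.kruskal_pair(grouped(groups))
        h, p = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(h, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_h_equals_z_squared_for_two_tie_free_groups(self, rng):
        a, b = rng.uniform(size=(2, 18))
        h = ps.kruskal_pair(grouped([a, b])).statistic
        res = ps.mwu_pair(grouped([a, b]), mode="asymptotic", continuity=False)
        n = 36
        z = res.effects["pearson_r"] * math.sqrt(n)
        assert h == pytest.approx(z * z, rel=1e-6)
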