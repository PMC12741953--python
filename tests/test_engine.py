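import numpy as np
import pytest

import pairstat as ps
from conftest import make_categorical, make_continuous, make_dichotomous


def _assert_bundles_identical(a, b):
    assert a.keys() == b.keys()
    for name in a.keys():
        np.testing.assert_array_equal(np.asarray(a[name], float),
                                      np.asarray(b[name], float))


class TestThreadInvariance:
    def test_pearson_bitwise_identical_across_threads(self):
        m = make_continuous(12, 50, 0.2, seed=2)
        bundles = [ps.pearson(m, threads=t,
                              requested_outputs=["statistic", "p_unadjusted", "r2"])
                   for t in (1, 2, 8)]
        _assert_bundles_identical(bundles[0], bundles[1])
        _assert_bundles_identical(bundles[0], bundles[2])

    def test_mixed_test_identical_across_threads(self):
        d = make_dichotomous(6, 50, 0.2, seed=3)
        x = make_continuous(7, 50, 0.2, seed=4)
        bundles = [ps.mwu(d, x, threads=t) for t in (1, 4)]
        _assert_bundles_identical(bundles[0], bundles[1])


class TestBundleContracts:
    @pytest.mark.parametrize("test,maker", [
        ("pearson", make_continuous), ("spearman", make_continuous),
    ])
    def test_homogeneous_symmetry(self, test, maker):
        m = maker(9, 40, 0.3, seed=6)
        b = ps.run_pairwise(test, m, requested_outputs=["statistic", "p_unadjusted"])
        for name in b.keys():
            M = b[name]
            np.testing.assert_array_equal(M, M.T)

    def test_chi2_symmetry(self):
        m = make_categorical(8, 80, 0.2, seed=7)
        b = ps.chi2(m)
        np.testing.assert_array_equal(b["statistic"], b["statistic"].T)

    def test_mixed_orientation(self):
        d = make_dichotomous(3, 30, 0.0, seed=8)
        x = make_continuous(5, 30, 0.0, seed=9)
        b = ps.ttest(d, x)
        assert b["statistic"].shape == (3, 5)

    def test_adjusted_diagonal_nan_and_unadjusted_self_test(self):
        m = make_continuous(6, 40, 0.1, seed=10)
        b = ps.pearson(m, requested_outputs=["statistic", "p_unadjusted",
                                             "p_bonferroni"])
        np.testing.assert_array_equal(np.diag(b["statistic"]), np.ones(6))
        np.testing.assert_array_equal(np.diag(b["p_unadjusted"]), np.zeros(6))
        assert np.isnan(np.diag(b["p_bonferroni"])).all()

    def test_invalid_output_name_lists_valid_ones(self):
        m = make_continuous(3, 20, 0.0, seed=1)
        with pytest.raises(ValueError, match="cohens_d"):
            ps.run_pairwise("ttest", make_dichotomous(2, 20, 0, 1),
                            make_continuous(2, 20, 0, 1),
                            requested_outputs=["nonsense"])

    def test_kind_and_shape_validation(self):
        cont = make_continuous(3, 20, 0.0, seed=1)
        with pytest.raises(ValueError, match="dichotomous"):
            ps.run_pairwise("ttest", cont, cont)
        with pytest.raises(ValueError, match="sample"):
            ps.ttest(make_dichotomous(2, 20, 0, 1), make_continuous(2, 21, 0, 1))
        with pytest.raises(ValueError, match="single input"):
            ps.run_pairwise("pearson", cont, cont)
        with pytest.raises(ValueError):
            ps.pearson(cont, threads=0)


class TestEngineMatchesScalarPath:
    """Matrix kernels must agree with the scalar per-pair functions."""

    def test_spearman_presort_equals_scalar_reranking(self):
        m = make_continuous(8, 35, 0.3, seed=12)
        X = m.values_with_nan()
        # inject ties to exercise tie-averaged subset re-ranking
        X[X < 0.3] = np.round(X[X < 0.3], 1)
        m = ps.validate_matrix(X, "continuous")
        b = ps.spearman(m)
        for i in range(8):
            for j in range(8):
                res = ps.spearman_pair(ps.joint_observed(X[i], X[j]))
                np.testing.assert_allclose(b["statistic"][i, j], res.statistic,
                                           rtol=1e-12, atol=1e-12, equal_nan=True)
                np.testing.assert_allclose(b["p_unadjusted"][i, j], res.p_value,
                                           rtol=1e-12, atol=1e-12, equal_nan=True)

    def test_mwu_presort_equals_scalar_ranking(self):
        d = make_dichotomous(5, 40, 0.25, seed=13)
        x = make_continuous(6, 40, 0.25, seed=14)
        X = x.values_with_nan()
        X[X > 0.7] = np.round(X[X > 0.7], 1)  # ties
        x = ps.validate_matrix(X, "continuous")
        b = ps.mwu(d, x, requested_outputs=["statistic", "p_unadjusted", "pearson_r"])
        for i in range(5):
            for j in range(6):
                po = ps.joint_observed(d.values_with_nan()[i], X[j])
                res = ps.mwu_pair(ps.group_by_label(po, expected_categories=2))
                np.testing.assert_allclose(b["statistic"][i, j], res.statistic,
                                           rtol=1e-12, atol=1e-12, equal_nan=True)
                np.testing.assert_allclose(b["p_unadjusted"][i, j], res.p_value,
                                           rtol=1e-12, atol=1e-12, equal_nan=True)

    def test_kruskal_engine_equals_scalar(self):
        c = make_categorical(5, 45, 0.2, seed=15)
        x = make_continuous(5, 45, 0.2, seed=16)
        b = ps.kruskal(c, x, requested_outputs=["statistic", "p_unadjusted", "eta2"])
        C = c.values_with_nan()
        for i in range(5):
            full_k = len(np.unique(C[i][~np.isnan(C[i])]))
            for j in range(5):
                po = ps.joint_observed(C[i], x.values_with_nan()[j])
                res = ps.kruskal_pair(ps.group_by_label(po, expected_categories=full_k))
                np.testing.assert_allclose(b["statistic"][i, j], res.statistic,
                                           rtol=1e-10, atol=1e-10, equal_nan=True)
                np.testing.assert_allclose(b["eta2"][i, j], res.effects["eta2"],
                                           rtol=1e-10, atol=1e-10, equal_nan=True)
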