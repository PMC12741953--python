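import numpy as np
import pytest

import pairstat as ps


class TestSimulateMatrix:
    def test_continuous_values_in_unit_interval(self):
        m = ps.simulate_matrix(ps.SimSpec(F=5, S=100, seed=1))
        assert ((m.values >= 0) & (m.values <= 1)).all()

    def test_every_category_present_per_feature(self):
        spec = ps.SimSpec(F=2, S=8, kind="categorical", c=4, miss_rate=0, seed=3)
        m = ps.simulate_matrix(spec)
        for row in m.values:
            assert set(row.astype(int)) == {0, 1, 2, 3}

    def test_reproducible_given_seed(self):
        spec = ps.SimSpec(F=4, S=50, kind="categorical", c=3, seed=11)
        a = ps.simulate_matrix(spec)
        b = ps.simulate_matrix(spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_dichotomous_implies_two_categories(self):
        m = ps.simulate_matrix(ps.SimSpec(F=3, S=20, kind="dichotomous", seed=2))
        assert set(np.unique(m.values)) == {0.0, 1.0}

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ps.SimSpec(F=1, S=3, kind="categorical", c=4)
        with pytest.raises(ValueError):
            ps.SimSpec(F=1, S=8, kind="categorical", c=4, miss_rate=0.8)
        with pytest.raises(ValueError):
            ps.SimSpec(F=1, S=10, miss_rate=1.0)
        with pytest.raises(ValueError):
            ps.SimSpec(F=1, S=10, mechanism="ODD")


class TestInjectMissing:
    def test_mcar_exact_count_per_feature(self):
        spec = ps.SimSpec(F=4, S=1000, miss_rate=0.1, seed=5)
        m = ps.inject_missing(ps.simulate_matrix(spec), spec)
        counts = m.missing_mask().sum(axis=1)
        np.testing.assert_array_equal(counts, 100)

    def test_zero_rate_is_identity(self):
        spec = ps.SimSpec(F=3, S=40, miss_rate=0.0, seed=6)
        full = ps.simulate_matrix(spec)
        out = ps.inject_missing(full, spec)
        np.testing.assert_array_equal(out.values, full.values)

    def test_rejects_already_missing_input(self):
        spec = ps.SimSpec(F=2, S=30, miss_rate=0.2, seed=7)
        m = ps.inject_missing(ps.simulate_matrix(spec), spec)
        with pytest.raises(ValueError):
            ps.inject_missing(m, spec)

    def test_mcar_mask_independent_of_values(self):
        spec = ps.SimSpec(F=10, S=1000, miss_rate=0.2, seed=8)
        full = ps.simulate_matrix(spec)
        out = ps.inject_missing(full, spec)
        mask = out.missing_mask()
        for f in range(10):
            corr = np.corrcoef(mask[f].astype(float), full.values[f])[0, 1]
            assert abs(corr) < 0.1

    @pytest.mark.parametrize("mechanism", ["MAR", "MNAR"])
    def test_logistic_mechanisms_hit_target_rate(self, mechanism):
        rates = []
        for rep in range(20):
            spec = ps.SimSpec(F=3, S=1000, miss_rate=0.15, mechanism=mechanism,
                              seed=100 + rep)
            m = ps.simulate_dataset(spec)
            rates.append(m.missing_mask().mean())
        assert abs(np.mean(rates) - 0.15) < 0.02

    def test_mnar_biases_observed_mean_downward(self):
        # missingness increases with the value itself, so the observed mean
        # must fall below the complete-data mean in almost every replicate
        deficits = []
        for rep in range(50):
            spec = ps.SimSpec(F=2, S=200, miss_rate=0.3, mechanism="MNAR",
                              seed=500 + rep)
            m = ps.simulate_dataset(spec)
            obs = m.values[~m.missing_mask()]
            deficits.append(obs.mean() - 0.5)
        assert np.mean(deficits) < -0.02
        assert (np.array(deficits) < 0).mean() > 0.9

    def test_mar_designated_driver_stays_observed(self):
        spec = ps.SimSpec(F=4, S=300, miss_rate=0.2, mechanism="MAR",
                          seed=9, driver_feature=0)
        m = ps.simulate_dataset(spec)
        mask = m.missing_mask()
        assert mask[0].sum() == 0
        assert mask[1:].sum() > 0

    def test_finite_sentinel_round_trip(self):
        spec = ps.SimSpec(F=3, S=100, miss_rate=0.1, na_value=-999.0, seed=10)
        m = ps.simulate_dataset(spec)
        assert (m.values == -999.0).sum() == m.missing_mask().sum() == 30
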