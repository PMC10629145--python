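"""Synthetic cohort generation, missingness injection, listwise deletion, I/O."""

import numpy as np
import pytest

import misspipe as mp
from misspipe.cohort import HIGH_MISSING_RATES


class TestGenerateCohort:
    def test_null_model_prevalence_near_half(self):
        spec = mp.SyntheticSpec.default(n=2000, d=10, support_size=0, seed=1)
        cohort = mp.generate_cohort(spec)
        se = np.sqrt(0.25 / 2000)
        assert abs(cohort.y.mean() - 0.5) < 3 * se

    def test_recipe_oracle_bit_identical(self):
        """Re-executing the documented sampling recipe reproduces the draw."""
        spec = mp.SyntheticSpec.default(n=1000, d=8, support_size=3,
                                        binary_fraction=0.25, corr=0.3, seed=42)
        cohort = mp.generate_cohort(spec)
        # independent re-implementation of the documented recipe
        rng = np.random.default_rng(42)
        e = rng.standard_normal((1000, 8))
        z = np.empty((1000, 8))
        z[:, 0] = e[:, 0]
        for j in range(1, 8):
            z[:, j] = 0.3 * z[:, j - 1] + np.sqrt(1 - 0.3**2) * e[:, j]
        X = z.copy()
        isbin = spec.schema.is_binary
        X[:, isbin] = (z[:, isbin] > 0).astype(float)
        eta = spec.intercept + X @ spec.beta_true
        y = (rng.random(1000) < 1 / (1 + np.exp(-eta))).astype(np.int64)
        np.testing.assert_array_equal(cohort.X, X)
        np.testing.assert_array_equal(cohort.y, y)

    def test_default_spec_has_nine_active_of_67(self):
        spec = mp.SyntheticSpec.default()
        assert spec.schema.d == 67
        assert int(np.count_nonzero(spec.beta_true)) == 9

    def test_binary_columns_are_binary(self):
        cohort = mp.generate_cohort(mp.SyntheticSpec.default(n=100, seed=3))
        isbin = cohort.schema.is_binary
        assert np.isin(cohort.X[:, isbin], (0.0, 1.0)).all()

    def test_rejects_bad_specs(self):
        schema = mp.FeatureSchema.default(d=4)
        with pytest.raises(ValueError):
            mp.SyntheticSpec(n=10, schema=schema, beta_true=np.ones(4),
                             intercept=0.0, support_size=2, corr=0.2)
        with pytest.raises(ValueError):
            mp.SyntheticSpec(n=10, schema=schema, beta_true=np.ones(4),
                             intercept=0.0, support_size=4, corr=1.0)

    def test_determinism(self):
        spec = mp.SyntheticSpec.default(n=200, d=12, support_size=4, seed=9)
        a, b = mp.generate_cohort(spec), mp.generate_cohort(spec)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)


class TestInjectMissingness:
    def test_zero_rates_are_a_noop(self):
        cohort = mp.generate_cohort(mp.SyntheticSpec.default(n=50, d=6,
                                                             support_size=2, seed=1))
        mspec = mp.MissingnessSpec(mechanism="mcar",
                                   per_feature_rate=np.zeros(6), seed=0)
        masked = mp.inject_missingness(cohort, mspec)
        assert masked.M.all()
        np.testing.assert_array_equal(masked.X_obs, cohort.X)

    def test_highest_profile_rate_realized(self):
        """The worst-observed feature's realized rate matches its 0.307 target."""
        cohort = mp.generate_cohort(mp.SyntheticSpec.default(n=5000, seed=2))
        masked = mp.inject_missingness(cohort, mp.default_missingness_profile(seed=3))
        realized = (~masked.M[:, 0]).mean()
        se = np.sqrt(0.307 * 0.693 / 5000)
        assert abs(realized - 0.307) < 3 * se

    def test_uniform_mcar_rate_matches_recount(self):
        cohort = mp.generate_cohort(mp.SyntheticSpec.default(n=400, d=10,
                                                             support_size=3, seed=4))
        mspec = mp.MissingnessSpec(mechanism="mcar",
                                   per_feature_rate=np.full(10, 0.0771), seed=5)
        masked = mp.inject_missingness(cohort, mspec)
        overall = (~masked.M).sum() / masked.M.size
        recount = np.isnan(masked.X_obs).sum() / masked.X_obs.size
        assert overall == recount

    def test_outcome_never_masked(self):
        cohort = mp.generate_cohort(mp.SyntheticSpec.default(n=100, seed=6))
        masked = mp.inject_missingness(cohort, mp.default_missingness_profile(seed=7))
        assert not np.isnan(masked.y.astype(float)).any()

    def test_mar_calibration_and_driver(self):
        cohort = mp.generate_cohort(mp.SyntheticSpec.default(
            n=4000, d=6, support_size=2, binary_fraction=0.0, seed=8))
        rates = np.array([0.3, 0.1, 0.1, 0.1, 0.1, 0.0])
        mspec = mp.MissingnessSpec(mechanism="mar", per_feature_rate=rates,
                                   driver_feature=5, seed=9)
        masked = mp.inject_missingness(cohort, mspec)
        realized = (~masked.M[:, 0]).mean()
        assert abs(realized - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 4000)
        assert masked.M[:, 5].all()
        # missingness depends on the driver: split at its median
        drv = cohort.X[:, 5]
        hi = (~masked.M[drv > np.median(drv), 0]).mean()
        lo = (~masked.M[drv <= np.median(drv), 0]).mean()
        assert hi > lo

    def test_mar_requires_driver(self):
        with pytest.raises(ValueError):
            mp.MissingnessSpec(mechanism="mar",
                               per_feature_rate=np.full(3, 0.1), seed=0)

    def test_rates_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            mp.MissingnessSpec(mechanism="mcar",
                               per_feature_rate=np.array([0.5, 1.0]), seed=0)


class TestDefaultProfile:
    def test_overall_and_row_rates(self):
        """The default profile hits the ~7.71% overall and ~77.5% row rates."""
        mspec = mp.default_missingness_profile()
        assert mspec.per_feature_rate.mean() == pytest.approx(0.0771, abs=1e-9)
        assert tuple(mspec.per_feature_rate[:5]) == HIGH_MISSING_RATES
        cohort = mp.generate_cohort(mp.SyntheticSpec.default(n=8000, seed=10))
        masked = mp.inject_missingness(cohort, mspec)
        assert (~masked.M).mean() == pytest.approx(0.0771, abs=0.01)
        assert (~masked.M.all(axis=1)).mean() == pytest.approx(0.7752, abs=0.02)


class TestListwiseDelete:
    def test_complete_input_identity(self):
        cohort = mp.generate_cohort(mp.SyntheticSpec.default(n=30, d=5,
                                                             support_size=2, seed=11))
        masked = mp.MaskedCohort(X_obs=cohort.X.copy(),
                                 M=np.ones_like(cohort.X, dtype=bool),
                                 y=cohort.y, schema=cohort.schema)
        out = mp.listwise_delete(masked)
        np.testing.assert_array_equal(out.X, cohort.X)
        np.testing.assert_array_equal(out.y, cohort.y)

    def test_toy_keeps_complete_rows_in_order(self):
        schema = mp.FeatureSchema(names=("a", "b", "c"),
                                  kinds=("continuous",) * 3)
        X = np.arange(12, dtype=float).reshape(4, 3)
        X[1, 2] = np.nan
        X[3, 0] = np.nan
        masked = mp.MaskedCohort(X_obs=X, M=~np.isnan(X),
                                 y=np.array([1, 0, 1, 0]), schema=schema)
        out = mp.listwise_delete(masked)
        np.testing.assert_array_equal(out.X, np.arange(12.).reshape(4, 3)[[0, 2]])
        np.testing.assert_array_equal(out.y, [1, 1])

    def test_profile_drops_near_three_quarters(self):
        cohort = mp.generate_cohort(mp.SyntheticSpec.default(n=6000, seed=12))
        masked = mp.inject_missingness(cohort,
                                       mp.default_missingness_profile(seed=13))
        kept = mp.listwise_delete(masked).n
        assert 1 - kept / cohort.n == pytest.approx(0.775, abs=0.03)

    def test_no_complete_rows_is_an_error(self):
        schema = mp.FeatureSchema(names=("a",), kinds=("continuous",))
        X = np.array([[np.nan], [np.nan]])
        masked = mp.MaskedCohort(X_obs=X, M=~np.isnan(X),
                                 y=np.array([0, 1]), schema=schema)
        with pytest.raises(ValueError):
            mp.listwise_delete(masked)

    def test_roundtrip_after_zero_rate_injection(self, mixed_masked):
        cohort, _ = mixed_masked
        mspec = mp.MissingnessSpec(mechanism="mcar",
                                   per_feature_rate=np.zeros(cohort.schema.d),
                                   seed=0)
        back = mp.listwise_delete(mp.inject_missingness(cohort, mspec))
        np.testing.assert_array_equal(back.X, cohort.X)


class TestCsvRoundtrip:
    def test_masked_roundtrip(self, tmp_path, mixed_masked):
        _, masked = mixed_masked
        path = tmp_path / "cohort.csv"
        mp.write_cohort(masked, path)
        back = mp.read_masked(path)
        np.testing.assert_allclose(
            back.X_obs[back.M], masked.X_obs[masked.M], rtol=1e-12)
        np.testing.assert_array_equal(back.M, masked.M)
        np.testing.assert_array_equal(back.y, masked.y)
        assert back.schema == masked.schema
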