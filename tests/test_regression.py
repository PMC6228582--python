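"""Strength regression: transforms, OLS, gradient descent, inference, variants."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from promstrength import (
    PromoterRecord,
    RegressionFit,
    adjusted_r2,
    feature_table,
    featurize,
    fit_gradient_descent,
    fit_ols,
    fit_variant_models,
    load_model,
    log_strength,
    model_stats,
    predict_log_strength,
    predict_strength,
    save_model,
    synthetic_feature_table,
)


class TestLogStrength:
    def test_reference_promoter(self):
        assert log_strength(1.0) == 0.0

    def test_weak_promoter(self):
        assert log_strength(0.01) == pytest.approx(-4.60517019, abs=1e-8)

    def test_floor_applies_at_zero(self):
        assert log_strength(0.0) == pytest.approx(math.log(1e-4), abs=1e-12)
        assert log_strength(0.0, floor=1e-2) == pytest.approx(math.log(1e-2), abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_strength(-0.1)


class TestFeaturize:
    def test_empty_records(self, pwm35, pwm10):
        table = featurize([], pwm35, pwm10)
        assert len(table) == 0
        assert list(table.columns) == ["id", "s35", "s10", "y"]

    def test_scores_and_response(self, pwm35, pwm10):
        rec = PromoterRecord("p1", "TTGACA", "TATAAT", 0.5)
        table = featurize([rec], pwm35, pwm10)
        assert table.s35[0] == pytest.approx(pwm35.score("TTGACA"))
        assert table.s10[0] == pytest.approx(pwm10.score("TATAAT"))
        assert table.y[0] == pytest.approx(math.log(0.5))


class TestOLS:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        s35, s10 = rng.normal(size=20), rng.normal(size=20)
        y = 1.0 + 2.0 * s35 - 3.0 * s10
        fit = fit_ols(feature_table(range(20), s35, s10, y))
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.beta35 == pytest.approx(2.0, abs=1e-10)
        assert fit.beta10 == pytest.approx(-3.0, abs=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        table = feature_table(
            range(50), rng.normal(size=50), rng.normal(size=50), rng.normal(size=50)
        )
        fit = fit_ols(table)
        resid = table.y.to_numpy() - fit.predict_table(table)
        assert abs(resid.sum()) < 1e-8
        assert abs(resid @ table.s35.to_numpy()) < 1e-8
        assert abs(resid @ table.s10.to_numpy()) < 1e-8

    def test_collinear_rejected(self):
        s35 = np.arange(10.0)
        table = feature_table(range(10), s35, 2 * s35, np.arange(10.0))
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(table)

    def test_too_few_rows_rejected(self):
        table = feature_table(range(3), [1.0, 2, 3], [3.0, 1, 2], [0.0, 1, 2])
        with pytest.raises(ValueError, match="at least"):
            fit_ols(table)

    def test_agrees_with_statsmodels(self, anderson_table):
        fit = fit_ols(anderson_table)
        X = sm.add_constant(anderson_table[["s35", "s10"]].to_numpy())
        ref = sm.OLS(anderson_table.y.to_numpy(), X).fit()
        np.testing.assert_allclose(
            [fit.intercept, fit.beta35, fit.beta10], ref.params, atol=1e-10
        )


class TestGradientDescent:
    def test_zero_response_stays_at_zero(self, anderson_table):
        table = anderson_table.copy()
        table["y"] = 0.0
        fit = fit_gradient_descent(table, iterations=500)
        assert fit.intercept == 0.0
        assert np.all(fit.slopes == 0.0)
        assert np.all(fit.cost_trajectory == 0.0)

    def test_converges_to_ols(self, anderson_table, anderson_fit):
        fit = fit_gradient_descent(anderson_table, learning_rate=0.015, iterations=100_000)
        assert fit.intercept == pytest.approx(anderson_fit.intercept, abs=1e-3)
        assert fit.beta35 == pytest.approx(anderson_fit.beta35, abs=1e-3)
        assert fit.beta10 == pytest.approx(anderson_fit.beta10, abs=1e-3)
        assert fit.fit_method == "gradient_descent"
        assert (fit.learning_rate, fit.iterations) == (0.015, 100_000)

    def test_divergence_detected(self, anderson_table):
        with pytest.raises(ValueError, match="diverging"):
            fit_gradient_descent(anderson_table, learning_rate=1.0, iterations=10_000)

    def test_feature_scaling_allows_larger_rate(self, anderson_table, anderson_fit):
        fit = fit_gradient_descent(
            anderson_table, learning_rate=0.5, iterations=5_000, feature_scaling=True
        )
        assert fit.intercept == pytest.approx(anderson_fit.intercept, abs=1e-6)
        assert fit.beta35 == pytest.approx(anderson_fit.beta35, abs=1e-6)

    def test_deterministic(self, anderson_table):
        a = fit_gradient_descent(anderson_table, iterations=2_000)
        b = fit_gradient_descent(anderson_table, iterations=2_000)
        assert a.intercept == b.intercept and np.all(a.slopes == b.slopes)


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(1.0, 18, 2) == 1.0

    def test_no_features_collapses(self):
        assert adjusted_r2(0.42, 10, 0) == pytest.approx(0.42, abs=1e-15)

    def test_training_scale_value(self):
        assert adjusted_r2(0.69, 18, 2) == pytest.approx(0.6487, abs=5e-5)

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 3, 2)


class TestModelStats:
    def test_agrees_with_statsmodels(self, anderson_table, anderson_fit):
        stats = model_stats(anderson_fit, anderson_table)
        X = sm.add_constant(anderson_table[["s35", "s10"]].to_numpy())
        ref = sm.OLS(anderson_table.y.to_numpy(), X).fit()
        np.testing.assert_allclose(stats.params["se"], ref.bse, atol=1e-10)
        np.testing.assert_allclose(stats.params["t"], ref.tvalues, atol=1e-10)
        np.testing.assert_allclose(stats.params["p"], ref.pvalues, atol=1e-12)
        np.testing.assert_allclose(
            stats.params[["ci_low", "ci_high"]].to_numpy(), ref.conf_int(0.05), atol=1e-10
        )
        assert stats.r2 == pytest.approx(ref.rsquared, abs=1e-12)
        assert stats.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-12)
        assert stats.f_statistic == pytest.approx(ref.fvalue, abs=1e-8)
        assert stats.f_pvalue == pytest.approx(ref.f_pvalue, abs=1e-12)

    def test_r2_equals_squared_correlation(self, anderson_table, anderson_fit):
        stats = model_stats(anderson_fit, anderson_table)
        fitted = anderson_fit.predict_table(anderson_table)
        r = np.corrcoef(fitted, anderson_table.y)[0, 1]
        assert stats.r2 == pytest.approx(r**2, abs=1e-10)
        assert stats.adj_r2 <= stats.r2

    def test_noiseless_data_warns_with_zero_width_ci(self):
        rng = np.random.default_rng(2)
        s35, s10 = rng.normal(size=10), rng.normal(size=10)
        table = feature_table(range(10), s35, s10, 0.5 + s35 - 2 * s10)
        fit = fit_ols(table)
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            stats = model_stats(fit, table)
        lo, hi = stats.ci("s35")
        assert lo == pytest.approx(hi, abs=1e-7) == pytest.approx(1.0, abs=1e-7)


class TestPredict:
    def test_intercept_only(self, anderson_fit):
        assert predict_strength(anderson_fit, 0.0, 0.0) == pytest.approx(
            math.exp(anderson_fit.intercept)
        )

    def test_linear_predictor(self):
        fit = RegressionFit(("s35", "s10"), -5.0, np.array([0.4, 0.3]))
        assert predict_log_strength(fit, 10.0, 10.0) == pytest.approx(2.0)
        assert predict_strength(fit, 10.0, 10.0) == pytest.approx(math.exp(2.0))

    def test_canonical_pair_predicts_above_reference(self, anderson_fit):
        # canonical TTGACA/TATAAT scores from the embedded training set
        strength = predict_strength(anderson_fit, 9.1308, 10.086)
        assert strength > 1.0
        assert strength == pytest.approx(4.6846, rel=1e-3)


class TestVariantModels:
    def test_variant_fits(self, anderson, anderson_table):
        vc = fit_variant_models(anderson_table, strengths=anderson.strengths())
        assert set(vc.summary.index) == {"main", "interaction", "combined", "raw_strength"}
        assert vc.summary.loc["interaction", "adj_r2"] < vc.summary.loc["main", "adj_r2"]
        # the interaction term carries no information in this dataset
        assert vc.stats["interaction"].params.loc["s35s10", "p"] > 0.9

    def test_interaction_recovered_when_present(self):
        table = synthetic_feature_table(n=60, sigma=0.3, seed=6)
        table["y"] = table["y"] + 0.15 * table["s35"] * table["s10"]
        vc = fit_variant_models(table)
        st = vc.stats["interaction"]
        assert st.params.loc["s35s10", "p"] < 0.05
        assert st.params.loc["s35s10", "coef"] == pytest.approx(0.15, abs=0.05)


class TestInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 50.0), seed=st.integers(0, 1000))
    def test_normalization_shifts_only_intercept(self, c, seed):
        """Rescaling all strengths by c changes the intercept by ln(c) and
        leaves the slopes untouched."""
        table = synthetic_feature_table(n=18, seed=seed)
        fit = fit_ols(table)
        scaled = table.copy()
        scaled["y"] = table["y"] + math.log(c)
        refit = fit_ols(scaled)
        assert refit.intercept == pytest.approx(fit.intercept + math.log(c), abs=1e-8)
        np.testing.assert_allclose(refit.slopes, fit.slopes, atol=1e-8)


class TestPersistence:
    def test_model_roundtrip(self, tmp_path, anderson_fit, anderson_table):
        path = tmp_path / "model.json"
        save_model(anderson_fit, path, stats=model_stats(anderson_fit, anderson_table))
        loaded = load_model(path)
        assert loaded.intercept == anderson_fit.intercept
        np.testing.assert_array_equal(loaded.slopes, anderson_fit.slopes)
        assert loaded.feature_names == anderson_fit.feature_names
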