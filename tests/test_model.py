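import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faindex.model import (
    DegenerateMetricsError,
    LassoConfig,
    Prediction,
    StratificationError,
    confusion_metrics,
    evaluate,
    fit_lasso_logistic,
    predict,
    predict_scores,
    published_model,
    riley_feasibility,
    validate,
)

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def newton_logistic_mle(X, y, iterations=200):
    """Independent unpenalized logistic MLE via Newton-Raphson."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X1.shape[1])
    for _ in range(iterations):
        eta = X1 @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        gradient = X1.T @ (y - p)
        hessian = X1.T @ (X1 * w[:, None])
        step = np.linalg.solve(hessian, gradient)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def riley_min_n_oracle(n_params, cs_r2, shrinkage):
    # Independent coding of the shrinkage criterion.
    return n_params / ((shrinkage - 1.0) * np.log1p(-cs_r2 / shrinkage))


def draw_from_published(rng, n):
    """Features from the study's index-scale group structure, labels from
    the published logit function."""
    half = n // 2
    o63 = np.concatenate([rng.normal(12.00, 4.94, half),
                          rng.normal(8.20, 2.60, n - half)])
    c18 = np.concatenate([rng.normal(0.42, 0.13, half),
                          rng.normal(0.275, 0.06, n - half)])
    X = pd.DataFrame({"o63bi": o63, "c18_ratio": c18})
    eta = 5.254 - 0.145 * o63 - 11.544 * c18
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return X, y, eta


class TestPublishedModel:
    def test_printed_constants(self):
        model = published_model()
        assert model.intercept == 5.254
        assert model.coefficients == {"o63bi": -0.145, "c18_ratio": -11.544}
        assert model.standardized_coefficients["o63bi"] == -0.622
        assert model.standardized_coefficients["c18_ratio"] == -1.416
        assert model.standardized_intercept == -0.147

    def test_aa_ada_recorded_as_excluded_with_zero_beta(self):
        model = published_model()
        assert "aa_ada" in model.excluded
        assert model.standardized_coefficients["aa_ada"] == 0.0

    def test_intercept_only_prediction(self):
        result = predict(published_model(), {"o63bi": 0.0, "c18_ratio": 0.0})
        assert result.logit_score == pytest.approx(5.254)


class TestPredict:
    def test_logit_zero_gives_half(self):
        from faindex.model import LogitModel

        model = LogitModel(intercept=0.0, coefficients={})
        assert predict(model, {}).probability == 0.5

    def test_control_mean_pseudo_sample(self):
        # 5.254 - 0.145*12.00 - 11.544*0.42 = -1.33448
        result = predict(published_model(), {"o63bi": 12.00, "c18_ratio": 0.42})
        assert result.logit_score == pytest.approx(-1.33448, abs=1e-10)
        assert result.probability == pytest.approx(
            1.0 / (1.0 + math.exp(1.33448)), abs=1e-10
        )
        assert result.probability == pytest.approx(0.2084, abs=5e-5)

    def test_probability_decreases_in_each_feature(self):
        model = published_model()
        base = predict(model, {"o63bi": 10.0, "c18_ratio": 0.3}).probability
        assert predict(model, {"o63bi": 11.0, "c18_ratio": 0.3}).probability < base
        assert predict(model, {"o63bi": 10.0, "c18_ratio": 0.4}).probability < base

    def test_affine_in_features_on_logit_scale(self):
        model = published_model()
        s = lambda a, b: predict(model, {"o63bi": a, "c18_ratio": b}).logit_score
        assert s(3.0, 0.2) - s(2.0, 0.2) == pytest.approx(s(1.0, 0.2) - s(0.0, 0.2))

    def test_missing_predictor_named(self):
        with pytest.raises(KeyError, match="c18_ratio"):
            predict(published_model(), {"o63bi": 1.0})

    def test_works_on_index_set_objects(self, control_pseudo_profile):
        from faindex.indices import compute_index_set

        index_set = compute_index_set(control_pseudo_profile)
        result = predict(published_model(), index_set)
        expected = 5.254 - 0.145 * index_set.o63bi - 11.544 * index_set.c18_ratio
        assert result.logit_score == pytest.approx(expected)


class TestFitLasso:
    def test_infinite_penalty_full_shrinkage(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        y = np.r_[np.ones(40), np.zeros(80)].astype(int)
        model = fit_lasso_logistic(X, y, LassoConfig(lambda_=math.inf))
        assert all(b == 0.0 for b in model.coefficients.values())
        prevalence = 40 / 120
        assert model.intercept == pytest.approx(
            math.log(prevalence / (1 - prevalence)), abs=1e-12
        )
        assert set(model.excluded) == {"a", "b", "c"}

    def test_zero_penalty_matches_newton_oracle(self, rng):
        n = 2000
        X = pd.DataFrame(
            {"a": rng.normal(0, 1, n), "b": rng.normal(0, 1.5, n)}
        )
        eta = -0.4 + 0.9 * X["a"] - 0.6 * X["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        model = fit_lasso_logistic(X, y, LassoConfig(lambda_=0.0))
        oracle = newton_logistic_mle(X.to_numpy(), y.to_numpy())
        assert model.intercept == pytest.approx(oracle[0], abs=1e-3)
        assert model.coefficients["a"] == pytest.approx(oracle[1], abs=1e-3)
        assert model.coefficients["b"] == pytest.approx(oracle[2], abs=1e-3)

    def test_parameter_recovery_from_published_model(self, rng):
        X, y, _ = draw_from_published(rng, 5000)
        model = fit_lasso_logistic(
            X, y, LassoConfig(n_lambdas=20, cv_folds=5, seed=3)
        )
        assert model.coefficients["o63bi"] == pytest.approx(-0.145, rel=0.10)
        assert model.coefficients["c18_ratio"] == pytest.approx(-11.544, rel=0.10)

    def test_constant_feature_dropped_with_warning(self, rng):
        X = pd.DataFrame(
            {"a": rng.normal(0, 1, 200), "flat": np.ones(200)}
        )
        y = (X["a"] > 0).astype(int)
        with pytest.warns(UserWarning, match="flat"):
            model = fit_lasso_logistic(X, y, LassoConfig(lambda_=0.01))
        assert "flat" not in model.coefficients

    def test_separable_data_sets_flag(self, rng):
        X = pd.DataFrame({"a": np.r_[rng.normal(-3, 0.1, 50),
                                     rng.normal(3, 0.1, 50)]})
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        model = fit_lasso_logistic(X, y, LassoConfig(lambda_=1e-4))
        assert model.separation_flag
        assert np.isfinite(model.coefficients["a"])

    def test_original_and_standardized_scales_consistent(self, rng):
        X = pd.DataFrame({"a": rng.normal(5, 2, 300), "b": rng.normal(0, 1, 300)})
        y = (rng.random(300) < 0.5).astype(int)
        y[:50] = 1
        model = fit_lasso_logistic(X, y, LassoConfig(lambda_=0.01, seed=0))
        scores = predict_scores(model, X)
        Xs = (X - X.mean()) / X.std(ddof=0)
        standardized_scores = model.standardized_intercept + sum(
            model.standardized_coefficients[name] * Xs[name] for name in X
        )
        assert np.allclose(scores, standardized_scores, atol=1e-10)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateMetricsError):
            fit_lasso_logistic(X, [1, 1, 1], LassoConfig(lambda_=0.1))


def _predictions_from_eta(eta):
    return [Prediction(float(e), float(1 / (1 + np.exp(-e)))) for e in eta]


class TestEvaluate:
    def test_perfect_predictions(self):
        eta = np.array([-20.0, -20.0, 20.0, 20.0])
        labels = [0, 0, 1, 1]
        metrics = evaluate(_predictions_from_eta(eta), labels)
        assert metrics.brier == pytest.approx(0.0, abs=1e-12)
        assert metrics.mcc == pytest.approx(1.0)
        assert metrics.confusion == (2, 0, 0, 2)

    def test_printed_confusion_matrix_summary(self):
        summary = confusion_metrics(tn=35, fp=13, fn=8, tp=42)
        assert round(summary["accuracy"], 3) == 0.786
        assert round(summary["sensitivity"], 3) == 0.840
        assert round(summary["specificity"], 3) == 0.729
        # Closed-form MCC of these counts (the source text prints 0.62,
        # inconsistent with its own matrix).
        expected_mcc = (42 * 35 - 13 * 8) / math.sqrt(55 * 50 * 48 * 43)
        assert summary["mcc"] == pytest.approx(expected_mcc, abs=1e-12)
        assert round(summary["mcc"], 4) == 0.5734

    def test_mcnemar_exact_on_printed_counts(self):
        # Discordant cells 13 and 8 -> exact binomial two-sided p ~ 0.383.
        eta = np.concatenate(
            [np.full(35, -1.0), np.full(13, 1.0),   # controls: tn, fp
             np.full(8, -1.0), np.full(42, 1.0)]    # cases: fn, tp
        )
        labels = np.r_[np.zeros(48), np.ones(50)].astype(int)
        metrics = evaluate(_predictions_from_eta(eta), labels, cutoff_logit=0.0)
        assert metrics.confusion == (35, 13, 8, 42)
        assert metrics.mcnemar_p == pytest.approx(
            stats.binomtest(8, 21, 0.5).pvalue, abs=1e-12
        )
        assert round(metrics.mcnemar_p, 3) == 0.383
        assert metrics.nir_p == pytest.approx(
            stats.binomtest(77, 98, 50 / 98, alternative="greater").pvalue,
            abs=1e-12,
        )

    def test_brier_bound_for_prevalence_predictor(self):
        labels = np.r_[np.zeros(50), np.ones(50)].astype(int)
        eta = np.zeros(100)  # p = 0.5 = prevalence
        metrics = evaluate(_predictions_from_eta(eta), labels)
        assert metrics.brier == pytest.approx(0.25, abs=1e-12)

    def test_calibration_slope_near_one_on_self_generated_data(self, rng):
        n = 10000
        eta = rng.normal(0.0, 1.5, n)
        labels = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        metrics = evaluate(_predictions_from_eta(eta), labels)
        assert metrics.calibration_slope == pytest.approx(1.0, abs=0.1)

    def test_pseudo_r2_behaviour(self, rng):
        n = 2000
        eta = rng.normal(0.0, 2.0, n)
        labels = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        metrics = evaluate(_predictions_from_eta(eta), labels)
        assert 0.0 < metrics.cox_snell_r2 < 1.0
        assert metrics.cox_snell_r2 < metrics.nagelkerke_r2 <= 1.0

    def test_single_class_raises(self):
        with pytest.raises(DegenerateMetricsError):
            evaluate(_predictions_from_eta(np.zeros(5)), [1, 1, 1, 1, 1])


class TestRiley:
    def test_events_per_parameter(self):
        report = riley_feasibility(200, 50, 2, anticipated_cs_r2=0.3)
        assert report.events_per_parameter == 25.0

    def test_required_n_increases_with_params(self):
        ns = [
            riley_feasibility(500, 100, p, anticipated_cs_r2=0.3).required_n
            for p in (1, 2, 4, 8)
        ]
        assert ns == sorted(ns) and len(set(ns)) == 4

    def test_matches_independent_oracle_at_study_numbers(self):
        report = riley_feasibility(102, 52, 2, anticipated_cs_r2=0.423)
        expected = riley_min_n_oracle(2, 0.423, 0.9)
        assert report.required_n == math.ceil(expected)
        assert report.passes == (102 >= math.ceil(expected))
        assert report.passes  # 102 subjects clear the ~32 minimum

    def test_domain_guards(self):
        with pytest.raises(ValueError):
            riley_feasibility(100, 0, 2, 0.3)
        with pytest.raises(ValueError):
            riley_feasibility(100, 50, 2, anticipated_cs_r2=0.95)


FAST = LassoConfig(n_lambdas=8, cv_folds=4, lambda_min_ratio=1e-3)


class TestValidate:
    def test_b_zero_corrected_equals_apparent(self, rng):
        X, y, _ = draw_from_published(rng, 120)
        report = validate(X, y, FAST, B=0, k=4, seed=1)
        assert report.corrected == report.apparent
        assert report.optimism == {"auc": 0.0, "brier": 0.0,
                                   "calibration_slope": 0.0}

    def test_permuted_labels_corrected_auc_near_half(self, rng):
        X, y, _ = draw_from_published(rng, 200)
        permuted = rng.permutation(y)
        report = validate(X, permuted, FAST, B=40, k=4, seed=2)
        assert report.corrected["auc"] == pytest.approx(0.5, abs=0.05)

    def test_mean_auc_optimism_nonnegative(self, rng):
        X, y, _ = draw_from_published(rng, 150)
        report = validate(X, y, FAST, B=40, k=4, seed=3)
        # Optimism is non-negative in expectation; allow 3 MC sigmas.
        assert report.optimism["auc"] > -0.03

    def test_cv_pools_out_of_fold_predictions(self, rng):
        X, y, _ = draw_from_published(rng, 200)
        report = validate(X, y, FAST, B=0, k=5, seed=4)
        assert 0.5 < report.cv["auc"] <= report.apparent["auc"] + 0.05
        assert 0.0 < report.cv["brier"] < 0.5

    def test_stratification_error_when_class_smaller_than_k(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        y = np.r_[np.ones(3), np.zeros(17)].astype(int)
        with pytest.raises(StratificationError):
            validate(X, y, FAST, B=0, k=5, seed=0)
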