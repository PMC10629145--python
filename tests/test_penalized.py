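"""Penalized logistic regression: likelihood, penalties, solvers, refits."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit

import misspipe as mp
from misspipe.penalized import (PenaltySpec, PenalizedLogit, cv_deviance_table,
                                fit_bar_logistic, fit_penalized_logistic,
                                lambda_max, logistic_neg_loglik, penalty_value,
                                refit_and_summarize, scad_derivative,
                                scad_penalty, select_lambda_bic,
                                select_lambda_cv, wald_summary_row)


def logistic_problem(seed=0, n=200, d=5, beta=None, intercept=0.2):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    if beta is None:
        beta = np.zeros(d)
        beta[: min(3, d)] = [1.0, -1.2, 0.8][: min(3, d)]
    y = (rng.random(n) < expit(intercept + X @ beta)).astype(float)
    return X, y


class TestNegLoglik:
    def test_null_coefficients_give_n_log2(self):
        X, y = logistic_problem(1, n=50)
        assert logistic_neg_loglik(X, y, np.zeros(6)) == pytest.approx(
            50 * np.log(2))

    def test_single_sample_closed_form(self):
        X = np.array([[1.0]])
        val = logistic_neg_loglik(X, np.array([1.0]), np.array([0.0, 0.5]))
        assert val == pytest.approx(-np.log(expit(0.5)), abs=1e-10)

    def test_matches_per_sample_bernoulli_oracle(self):
        X, y = logistic_problem(2, n=4, d=3)
        beta = np.array([0.1, -0.4, 0.7, 0.2])
        p = expit(beta[0] + X @ beta[1:])
        oracle = -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert logistic_neg_loglik(X, y, beta) == pytest.approx(oracle)


class TestPenaltyValue:
    @pytest.mark.parametrize("family", ["lasso", "elasticnet", "scad", "ridge"])
    def test_zero_beta_gives_zero(self, family):
        assert penalty_value(np.zeros(4), PenaltySpec(family=family,
                                                      lam=2.0)) == 0.0

    def test_lasso_hand_sum(self):
        assert penalty_value(np.array([1.0, -2.0]),
                             PenaltySpec(family="lasso", lam=0.5)) == 1.5

    def test_elasticnet_mixes_l1_l2(self):
        spec = PenaltySpec(family="elasticnet", lam=1.0, mix=0.5)
        b = np.array([2.0, -1.0])
        assert penalty_value(b, spec) == pytest.approx(0.5 * 3 + 0.25 * 5)

    def test_scad_derivative_flat_beyond_a_lam(self):
        assert scad_derivative(np.array([5.0]), 1.0, 3.7)[0] == 0.0

    def test_scad_equals_lasso_near_zero_and_flat_far(self):
        lam, a = 1.5, 3.7
        t = np.array([0.3, 1.0, 1.5])
        np.testing.assert_allclose(scad_derivative(t, lam, a), lam)
        np.testing.assert_allclose(scad_penalty(t, lam, a), lam * t)
        assert scad_penalty(np.array([10.0]), lam, a)[0] == pytest.approx(
            lam**2 * (a + 1) / 2)

    def test_scad_penalty_integrates_its_derivative(self):
        lam, a = 1.0, 3.7
        grid = np.linspace(0, 6, 6001)
        integral = np.cumsum(scad_derivative(grid, lam, a)) * (grid[1] - grid[0])
        np.testing.assert_allclose(scad_penalty(grid, lam, a), integral,
                                   atol=2e-3)


def ista_oracle(X, y, spec, max_iter=30_000, tol=1e-12):
    """Independent proximal-gradient solver for the L1/L2-penalized logistic
    objective on standardized columns (matching the solver's internal scale)."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    n, d = Xs.shape
    l1 = spec.lam * (spec.mix if spec.family == "elasticnet" else 1.0)
    l2 = spec.lam * (1 - spec.mix) if spec.family == "elasticnet" else 0.0
    if spec.family == "none":
        l1 = 0.0
    beta = np.zeros(d + 1)
    A = np.column_stack([np.ones(n), Xs])
    L = 0.25 * np.linalg.norm(A, 2) ** 2 + l2
    obj_prev = np.inf
    for _ in range(max_iter):
        p = expit(A @ beta)
        grad = A.T @ (p - y)
        grad[1:] += l2 * beta[1:]
        z = beta - grad / L
        beta_new = z.copy()
        beta_new[1:] = np.sign(z[1:]) * np.maximum(np.abs(z[1:]) - l1 / L, 0)
        eta = A @ beta_new
        obj = (np.sum(np.logaddexp(0, eta)) - y @ eta
               + l1 * np.abs(beta_new[1:]).sum()
               + 0.5 * l2 * (beta_new[1:] ** 2).sum())
        beta = beta_new
        if abs(obj_prev - obj) < tol:
            break
        obj_prev = obj
    return beta, obj


def penalized_objective_std(X, y, res, spec):
    """Objective of a fitted result on the standardized scale."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    bs = res.params[1:] * X.std(axis=0)
    b0 = res.params[0] + res.params[1:] @ X.mean(axis=0)
    eta = b0 + Xs @ bs
    l1 = spec.lam * (spec.mix if spec.family == "elasticnet" else 1.0)
    l2 = spec.lam * (1 - spec.mix) if spec.family == "elasticnet" else 0.0
    return (np.sum(np.logaddexp(0, eta)) - y @ eta
            + l1 * np.abs(bs).sum() + 0.5 * l2 * (bs**2).sum())


class TestCoordinateDescent:
    def test_lam_zero_matches_unpenalized_mle(self):
        X, y = logistic_problem(3)
        res = fit_penalized_logistic(X, y, PenaltySpec(family="none", lam=0.0))
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(res.params, mle.params, atol=1e-6)

    @pytest.mark.parametrize("family,lam", [("lasso", 3.0), ("lasso", 10.0),
                                            ("elasticnet", 5.0)])
    def test_objective_matches_proximal_gradient_oracle(self, family, lam):
        X, y = logistic_problem(4, n=50, d=5)
        spec = PenaltySpec(family=family, lam=lam)
        res = fit_penalized_logistic(X, y, spec)
        _, obj_oracle = ista_oracle(X, y, spec)
        assert penalized_objective_std(X, y, res, spec) == pytest.approx(
            obj_oracle, abs=1e-6)

    def test_above_lambda_max_gives_null_model(self):
        X, y = logistic_problem(5)
        lam = lambda_max(X, y) * 1.001
        res = fit_penalized_logistic(X, y, PenaltySpec(family="lasso", lam=lam))
        assert np.all(res.params[1:] == 0.0)
        just_below = lambda_max(X, y) * 0.95
        res2 = fit_penalized_logistic(X, y,
                                      PenaltySpec(family="lasso", lam=just_below))
        assert res2.support_size >= 1

    def test_single_coordinate_solution_is_soft_thresholded(self):
        """1-D lasso matches the proximal (soft-threshold) oracle, and the
        coefficient dies exactly once the threshold exceeds the null score."""
        X, y = logistic_problem(6, d=1, beta=np.array([0.9]), intercept=0.0)
        spec = PenaltySpec(family="lasso", lam=8.0)
        res = fit_penalized_logistic(X, y, spec)
        beta_oracle, _ = ista_oracle(X, y, spec)
        bs = res.params[1] * X.std()
        assert bs == pytest.approx(beta_oracle[1], abs=1e-5)
        # score at the null model is the exact kill threshold
        Xs = (X - X.mean()) / X.std()
        score = abs(float(Xs[:, 0] @ (y - y.mean())))
        dead = fit_penalized_logistic(X, y, PenaltySpec(family="lasso",
                                                        lam=score * 1.0001))
        alive = fit_penalized_logistic(X, y, PenaltySpec(family="lasso",
                                                         lam=score * 0.98))
        assert dead.params[1] == 0.0
        assert alive.params[1] != 0.0

    def test_objective_traces_nonincreasing(self):
        X, y = logistic_problem(7)
        for family, lam in [("lasso", 2.0), ("elasticnet", 2.0), ("scad", 2.0)]:
            res = fit_penalized_logistic(X, y, PenaltySpec(family=family,
                                                           lam=lam))
            tr = res.objective_trace
            assert all(b <= a + 1e-10 for a, b in zip(tr, tr[1:]))

    def test_zero_variance_column_rejected_by_name(self):
        X, y = logistic_problem(8, d=3)
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="1"):
            fit_penalized_logistic(X, y, PenaltySpec(family="lasso", lam=1.0))


class TestScad:
    def test_scad_unbiasedness_keeps_large_coefficients_closer(self):
        """SCAD applies no shrinkage to large coefficients; its estimate of a
        strong signal exceeds the lasso estimate at the same lam."""
        X, y = logistic_problem(9, n=800, d=4, beta=np.array([2.0, 0, 0, 0]))
        lam = 8.0
        scad = fit_penalized_logistic(X, y, PenaltySpec(family="scad", lam=lam))
        lasso = fit_penalized_logistic(X, y, PenaltySpec(family="lasso", lam=lam))
        assert scad.params[1] > lasso.params[1]


class TestBar:
    def test_lam_zero_reduces_to_mle(self):
        X, y = logistic_problem(10)
        res = fit_bar_logistic(X, y, PenaltySpec(family="bar", lam=0.0,
                                                 bar_ridge_lam=0.0))
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(res.params, mle.params, atol=1e-6)

    def test_solutions_exactly_sparse(self):
        X, y = logistic_problem(11, n=400, d=10)
        res = fit_bar_logistic(X, y, PenaltySpec(family="bar", lam=6.0))
        slopes = res.params[1:]
        assert np.all((slopes == 0.0) | (np.abs(slopes) > 1e-6))
        assert 0 < res.support_size < 10

    def test_outer_steps_descend_their_weighted_objective(self):
        X, y = logistic_problem(12, n=300, d=6)
        res = fit_bar_logistic(X, y, PenaltySpec(family="bar", lam=4.0))
        assert res.step_objectives
        assert all(end <= start + 1e-10 for start, end in res.step_objectives)


class TestLambdaSelection:
    def test_single_value_grid_returned(self):
        X, y = logistic_problem(13)
        spec = select_lambda_cv(X, y, PenaltySpec(family="lasso"), [0.7],
                                folds=3, seed=0)
        assert spec.lam == 0.7

    def test_cv_deterministic(self):
        X, y = logistic_problem(14)
        grid = [0.5, 2.0, 8.0]
        a = select_lambda_cv(X, y, PenaltySpec(family="lasso"), grid, seed=3)
        b = select_lambda_cv(X, y, PenaltySpec(family="lasso"), grid, seed=3)
        assert a.lam == b.lam

    def test_chosen_lam_is_argmin_of_recomputed_table(self):
        X, y = logistic_problem(15)
        grid = np.array([0.5, 2.0, 8.0, 30.0])
        spec = PenaltySpec(family="lasso")
        chosen = select_lambda_cv(X, y, spec, grid, folds=4, seed=1)
        table = cv_deviance_table(X, y, spec, grid, folds=4, seed=1)
        assert chosen.lam == grid[np.isclose(table, table.min())].max()

    def test_bic_prefers_sparser_fit_on_sparse_truth(self):
        X, y = logistic_problem(16, n=600, d=8)
        spec = select_lambda_bic(X, y, PenaltySpec(family="bar"),
                                 np.geomspace(0.5, 20, 5))
        res = fit_bar_logistic(X, y, spec)
        assert res.support_size <= 5


class TestRiskFactorTable:
    @pytest.mark.parametrize("beta,expected_or", [
        (0.34, 1.40), (1.24, 3.46), (0.28, 1.32), (0.37, 1.45)])
    def test_odds_ratio_consistency(self, beta, expected_or):
        row = wald_summary_row(beta, se=0.1)
        assert round(row["odds_ratio"], 2) == expected_or

    def test_null_coefficient_symmetric_ci(self):
        row = wald_summary_row(0.0, se=0.2)
        assert row["odds_ratio"] == 1.0
        assert np.log(row["or_ci_high"]) == pytest.approx(
            -np.log(row["or_ci_low"]))

    def test_refit_matches_statsmodels(self):
        X, y = logistic_problem(17, n=300, d=5)
        table = refit_and_summarize(X, y, [0, 1, 2],
                                    feature_names=list("abcde"))
        fit = sm.Logit(y, sm.add_constant(X[:, :3])).fit(disp=0)
        np.testing.assert_allclose(table.frame["beta"], fit.params, atol=1e-8)
        np.testing.assert_allclose(table.frame["odds_ratio"],
                                   np.exp(fit.params), rtol=1e-10)
        assert list(table.frame["factor"]) == ["intercept", "a", "b", "c"]
        assert not table.separation

    def test_empty_support_rejected(self):
        X, y = logistic_problem(18)
        with pytest.raises(ValueError):
            refit_and_summarize(X, y, [])

    def test_tsv_has_table_columns(self):
        X, y = logistic_problem(19, n=200, d=3)
        text = refit_and_summarize(X, y, [0, 1]).to_tsv()
        assert text.splitlines()[0] == "Factor\tbeta\tWald\tOR(95% CI)\tP"


class TestModelResultsApi:
    def test_from_dataframe_and_summary(self):
        import pandas as pd
        X, y = logistic_problem(20, n=150, d=3)
        df = pd.DataFrame(X, columns=["age", "parity", "bmi"])
        df["outcome"] = y
        model = PenalizedLogit.from_dataframe(df,
                                              penalty=PenaltySpec(family="lasso",
                                                                  lam=2.0))
        res = model.fit()
        assert "lasso" in res.summary()
        assert res.feature_names == ["age", "parity", "bmi"]
        probs = res.predict(X)
        assert probs.shape == (150,) and ((0 <= probs) & (probs <= 1)).all()
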