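"""Penalized logistic regression for simultaneous selection and estimation.

The estimator minimizes ``-l(beta) + P_lambda(beta)`` where ``l`` is the
Bernoulli log-likelihood under the logit link and ``P_lambda`` is one of

* LASSO            ``lam * sum |beta_j|``
* Elastic Net      ``lam * (mix * sum|beta_j| + (1-mix)/2 * sum beta_j^2)``
* SCAD             the folded-concave penalty with shape ``a`` (default 3.7)
* ridge            ``lam/2 * sum beta_j^2``
* BAR              broken adaptive ridge — iteratively reweighted ridge
                   approximating the L0 penalty, yielding exactly sparse fits

The intercept is never penalized and columns are standardized internally;
coefficients are reported on the original scale.  LASSO/Elastic-Net use
cyclic coordinate descent on the IRLS quadratic surrogate with
soft-thresholding; SCAD wraps the same engine in a local linear approximation
(majorize-minimize on reweighted L1); BAR alternates adaptively weighted
ridge fits with permanent freezing of near-zero coordinates.

Exposed in the statsmodels idiom: :class:`PenalizedLogit` is the model,
``fit()`` returns :class:`PenalizedLogitResults` (estimates, support,
convergence diagnostics, ``summary()``); :func:`refit_and_summarize` gives
the post-selection unpenalized refit as an odds-ratio risk-factor table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold

_FAMILIES = ("lasso", "elasticnet", "scad", "bar", "ridge", "none")
_W_FLOOR = 1e-5          # IRLS weight floor
_INNER_TOL = 1e-10       # coordinate-sweep convergence


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family and tuning constants."""

    family: str = "lasso"
    lam: float = 1.0
    scad_a: float = 3.7
    mix: float = 0.5               # elastic-net L1 proportion
    bar_ridge_lam: float = 1.0     # ridge parameter of the BAR initializer
    tol: float = 1e-6
    max_iter: int = 50             # outer iterations (BAR / SCAD-LLA)
    inner_max_iter: int = 1000
    zero_eps: float = 1e-6         # support threshold / BAR freezing rule

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.scad_a <= 2:
            raise ValueError("the SCAD shape parameter must exceed 2")
        if not 0 <= self.mix <= 1:
            raise ValueError("elastic-net mix must lie in [0, 1]")
        if self.zero_eps <= 0:
            raise ValueError("zero_eps must be positive")


# ---------------------------------------------------------------------------
# likelihood and penalties
# ---------------------------------------------------------------------------


def logistic_neg_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """``-sum_i [y_i eta_i - log(1 + e^{eta_i})]`` with intercept-first beta."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (X.shape[1] + 1,):
        raise ValueError("beta must have length d+1 (intercept first)")
    eta = beta[0] + X @ beta[1:]
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def scad_penalty(t: np.ndarray, lam: float, a: float) -> np.ndarray:
    """SCAD penalty at |t|: linear near zero, quadratic blend, then flat."""
    t = np.abs(np.asarray(t, dtype=float))
    lin = lam * t
    quad = (2 * a * lam * t - t**2 - lam**2) / (2 * (a - 1))
    flat = lam**2 * (a + 1) / 2
    return np.where(t <= lam, lin, np.where(t <= a * lam, quad, flat))


def scad_derivative(t: np.ndarray, lam: float, a: float) -> np.ndarray:
    """d/dt SCAD(|t|): ``lam`` for |t|<=lam, then ``(a lam - t)_+/(a-1)``."""
    t = np.abs(np.asarray(t, dtype=float))
    with np.errstate(invalid="ignore"):
        tail = np.maximum(a * lam - t, 0.0) / (a - 1)
    return np.where(t <= lam, lam, tail)


def penalty_value(beta: np.ndarray, spec: PenaltySpec) -> float:
    """Penalty of a slope vector (intercept excluded by the caller)."""
    b = np.asarray(beta, dtype=float)
    lam = spec.lam
    if spec.family in ("none", "bar"):
        return 0.0
    if spec.family == "lasso":
        return float(lam * np.abs(b).sum())
    if spec.family == "elasticnet":
        return float(lam * (spec.mix * np.abs(b).sum()
                            + 0.5 * (1 - spec.mix) * (b**2).sum()))
    if spec.family == "ridge":
        return float(0.5 * lam * (b**2).sum())
    if spec.family == "scad":
        return float(scad_penalty(b, lam, spec.scad_a).sum())
    raise ValueError(spec.family)


def lambda_max(X: np.ndarray, y: np.ndarray, mix: float = 1.0) -> float:
    """Smallest lam at which the L1-penalized fit is the null model.

    Computed on internally standardized columns as the largest absolute
    score-function entry at the intercept-only fit.
    """
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    g = np.abs(Xs.T @ (y - y.mean()))
    if mix <= 0:
        raise ValueError("lambda_max needs a positive L1 proportion")
    return float(g.max() / mix)


# ---------------------------------------------------------------------------
# core solvers (standardized scale)
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance column(s) at index {dead.tolist()}")
    return (X - mean) / sd, mean, sd


def _pen_objective(Xs, y, b0, b, l1w, l2w) -> float:
    eta = b0 + Xs @ b
    nll = float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)
    return nll + float(l1w @ np.abs(b)) + 0.5 * float(l2w @ b**2)


def _soft(z: float, g: float) -> float:
    return np.sign(z) * max(abs(z) - g, 0.0)


def _cd_weighted(Xs, y, l1w, l2w, b0, b, tol, max_outer, max_inner):
    """IRLS + cyclic coordinate descent for a weighted elastic-net logistic fit.

    Returns (b0, b, trace, converged); the recorded objective trace is
    nonincreasing (a step-halving safeguard backtracks any IRLS overshoot).
    """
    n, d = Xs.shape
    b = b.copy()
    obj = _pen_objective(Xs, y, b0, b, l1w, l2w)
    trace = [obj]
    converged = False
    for _ in range(max_outer):
        eta = b0 + Xs @ b
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.maximum(p * (1 - p), _W_FLOOR)
        z = eta + (y - p) / w
        denom = (w[:, None] * Xs**2).sum(axis=0)
        w_sum = w.sum()
        r = z - eta
        b0_prev, b_prev = b0, b.copy()
        for _ in range(max_inner):
            delta = 0.0
            new0 = b0 + (w @ r) / w_sum
            r += b0 - new0
            delta = max(delta, abs(new0 - b0))
            b0 = new0
            for j in range(d):
                xj = Xs[:, j]
                rho = xj @ (w * r) + denom[j] * b[j]
                new = _soft(rho, l1w[j]) / (denom[j] + l2w[j])
                if new != b[j]:
                    r += xj * (b[j] - new)
                    delta = max(delta, abs(new - b[j]))
                    b[j] = new
            if delta < _INNER_TOL:
                break
        new_obj = _pen_objective(Xs, y, b0, b, l1w, l2w)
        shrink = 0
        while new_obj > obj + 1e-12 and shrink < 30:   # backtrack overshoot
            b0 = 0.5 * (b0 + b0_prev)
            b = 0.5 * (b + b_prev)
            new_obj = _pen_objective(Xs, y, b0, b, l1w, l2w)
            shrink += 1
        if shrink == 30 and new_obj > obj + 1e-12:
            b0, b, new_obj = b0_prev, b_prev, obj
            trace.append(new_obj)
            converged = True
            break
        trace.append(new_obj)
        if abs(obj - new_obj) <= tol * (abs(obj) + 1.0):
            converged = True
            obj = new_obj
            break
        obj = new_obj
    return b0, b, trace, converged


def _fit_cd_family(Xs, y, spec: PenaltySpec):
    """Dispatch lasso / elasticnet / ridge / none / scad on standardized data."""
    d = Xs.shape[1]
    lam = spec.lam
    if spec.family in ("lasso", "none"):
        l1 = np.full(d, lam if spec.family == "lasso" else 0.0)
        l2 = np.zeros(d)
    elif spec.family == "elasticnet":
        l1 = np.full(d, lam * spec.mix)
        l2 = np.full(d, lam * (1 - spec.mix))
    elif spec.family == "ridge":
        l1 = np.zeros(d)
        l2 = np.full(d, lam)
    else:
        raise ValueError(spec.family)
    b0 = float(np.log(y.mean() / (1 - y.mean()))) if 0 < y.mean() < 1 else 0.0
    return _cd_weighted(Xs, y, l1, l2, b0, np.zeros(d),
                        spec.tol, 200, spec.inner_max_iter)


def _fit_scad(Xs, y, spec: PenaltySpec):
    """Local linear approximation: reweighted-L1 wraps the CD engine."""
    lam, a = spec.lam, spec.scad_a
    b0, b, _, _ = _fit_cd_family(Xs, y, replace(spec, family="lasso"))
    l2 = np.zeros(Xs.shape[1])

    def scad_obj(b0_, b_):
        eta = b0_ + Xs @ b_
        nll = float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)
        return nll + float(scad_penalty(b_, lam, a).sum())

    trace = [scad_obj(b0, b)]
    converged = False
    for _ in range(spec.max_iter):
        l1 = scad_derivative(b, lam, a)
        b0_new, b_new, _, _ = _cd_weighted(
            Xs, y, l1, l2, b0, b, spec.tol, 200, spec.inner_max_iter)
        new_obj = scad_obj(b0_new, b_new)
        if new_obj > trace[-1] + 1e-12:        # MM safeguard: keep the majorant
            converged = True
            break
        delta = max(abs(b0_new - b0), float(np.max(np.abs(b_new - b))) if b.size else 0.0)
        b0, b = b0_new, b_new
        trace.append(new_obj)
        if delta < spec.tol:
            converged = True
            break
    return b0, b, trace, converged


def _fit_bar(Xs, y, spec: PenaltySpec):
    """Broken adaptive ridge: ridge init, reweighted ridge, freeze-at-zero.

    The trace records the L0 surrogate ``-l(beta) + lam/2 * #active`` which
    the iteration approximates at its fixed point; it is a diagnostic, not a
    descent objective (the iteration is a fixed point, not a minimization of
    one fixed function).  The guaranteed descent property — each outer step
    lowers its own adaptively weighted objective — is returned as
    ``step_objectives`` pairs (value at the step's start and end under that
    step's weights).
    """
    d = Xs.shape[1]
    b0, b, _, _ = _fit_cd_family(Xs, y, replace(
        spec, family="ridge", lam=spec.bar_ridge_lam))
    active = np.abs(b) >= spec.zero_eps
    b[~active] = 0.0

    def surrogate(b0_, b_, n_active):
        eta = b0_ + Xs @ b_
        nll = float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)
        return nll + 0.5 * spec.lam * n_active

    trace = []
    step_objectives: list[tuple[float, float]] = []
    converged = False
    for _ in range(spec.max_iter):
        prev = b.copy()
        idx = np.flatnonzero(active)
        if idx.size:
            l2 = spec.lam / prev[idx] ** 2
            l1 = np.zeros(idx.size)
            start_val = _pen_objective(Xs[:, idx], y, b0, prev[idx],
                                       np.zeros(idx.size), l2)
            b0, b_sub, _, _ = _cd_weighted(
                Xs[:, idx], y, l1, l2, b0, prev[idx],
                min(spec.tol, 1e-8), 100, spec.inner_max_iter)
            end_val = _pen_objective(Xs[:, idx], y, b0, b_sub,
                                     np.zeros(idx.size), l2)
            step_objectives.append((start_val, end_val))
            b = np.zeros(d)
            b[idx] = b_sub
        else:
            b0, _, _, _ = _cd_weighted(
                Xs[:, :0], y, np.empty(0), np.empty(0), b0, np.empty(0),
                spec.tol, 100, spec.inner_max_iter)
            b = np.zeros(d)
        newly_dead = active & (np.abs(b) < spec.zero_eps)
        b[newly_dead] = 0.0                     # frozen at exactly zero
        active &= ~newly_dead
        trace.append(surrogate(b0, b, int(active.sum())))
        if float(np.max(np.abs(b - prev), initial=0.0)) < spec.tol:
            converged = True
            break
    return b0, b, trace, converged, step_objectives


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


@dataclass
class PenalizedLogitResults:
    """Fit results: estimates on the original scale, support, diagnostics."""

    params: np.ndarray                  # length d+1, intercept first
    support: np.ndarray                 # 0-based feature indices, |beta| > zero_eps
    lam_used: float
    n_iter: int
    converged: bool
    objective_trace: list[float]
    spec: PenaltySpec
    feature_names: list[str] | None = None
    model: "PenalizedLogit | None" = field(default=None, repr=False)
    #: BAR only: (start, end) of each outer step's weighted objective;
    #: end <= start is the iteration's guaranteed descent property.
    step_objectives: list[tuple[float, float]] = field(default_factory=list)

    @property
    def support_size(self) -> int:
        return int(self.support.size)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted event probabilities."""
        eta = self.params[0] + np.asarray(X, dtype=float) @ self.params[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))

    def summary(self) -> str:
        names = self.feature_names or [f"x{j}" for j in range(self.params.size - 1)]
        lines = [
            f"Penalized logistic regression ({self.spec.family}, "
            f"lam={self.lam_used:g})",
            f"converged: {self.converged}   iterations: {self.n_iter}   "
            f"selected: {self.support_size}/{self.params.size - 1}",
            f"{'term':<24}{'coef':>12}",
            f"{'intercept':<24}{self.params[0]:>12.4f}",
        ]
        for j in self.support:
            lines.append(f"{names[j]:<24}{self.params[j + 1]:>12.4f}")
        return "\n".join(lines)

    def risk_factor_table(self) -> "RiskFactorTable":
        if self.model is None:
            raise ValueError("results are detached from their model data")
        return refit_and_summarize(
            self.model.exog, self.model.endog, self.support,
            feature_names=self.feature_names,
        )


#: Spec-facing alias: a penalized fit *is* the selection result.
SelectionResult = PenalizedLogitResults


class PenalizedLogit:
    """Penalized logistic regression model (endog = binary outcome, exog = X)."""

    def __init__(self, endog, exog, penalty: PenaltySpec | None = None,
                 feature_names: list[str] | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.endog.shape != (self.exog.shape[0],):
            raise ValueError("exog must be n x d with endog of length n")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary")
        self.penalty = penalty or PenaltySpec()
        self.feature_names = list(feature_names) if feature_names else None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "outcome",
                       penalty: PenaltySpec | None = None) -> "PenalizedLogit":
        y = df[outcome].to_numpy()
        X = df.drop(columns=[outcome])
        return cls(y, X.to_numpy(dtype=float), penalty=penalty,
                   feature_names=list(X.columns))

    def fit(self, lam: float | None = None) -> PenalizedLogitResults:
        spec = self.penalty if lam is None else replace(self.penalty, lam=lam)
        Xs, mean, sd = _standardize(self.exog)
        y = self.endog
        step_objectives: list[tuple[float, float]] = []
        if spec.family == "bar":
            b0, b, trace, converged, step_objectives = _fit_bar(Xs, y, spec)
        elif spec.family == "scad":
            b0, b, trace, converged = _fit_scad(Xs, y, spec)
        else:
            b0, b, trace, converged = _fit_cd_family(Xs, y, spec)
        if not converged:
            warnings.warn(f"{spec.family} fit did not converge; result flagged")
        slopes = b / sd
        if spec.family == "bar":                 # exact sparsity on both scales
            slopes[np.abs(slopes) <= spec.zero_eps] = 0.0
        intercept = b0 - float(slopes @ mean)
        params = np.concatenate([[intercept], slopes])
        support = np.flatnonzero(np.abs(slopes) > spec.zero_eps)
        return PenalizedLogitResults(
            params=params, support=support, lam_used=spec.lam,
            n_iter=len(trace), converged=converged, objective_trace=trace,
            spec=spec, feature_names=self.feature_names, model=self,
            step_objectives=step_objectives,
        )


def fit_penalized_logistic(X, y, spec: PenaltySpec) -> PenalizedLogitResults:
    """Functional entry point for lasso / elasticnet / scad / ridge / none."""
    if spec.family == "bar":
        raise ValueError("use fit_bar_logistic for the BAR family")
    return PenalizedLogit(y, X, penalty=spec).fit()


def fit_bar_logistic(X, y, spec: PenaltySpec) -> PenalizedLogitResults:
    """Functional entry point for the broken-adaptive-ridge family."""
    return PenalizedLogit(y, X, penalty=replace(spec, family="bar")).fit()


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------


def cv_deviance_table(X, y, spec: PenaltySpec, grid, folds: int = 5,
                      seed: int = 0) -> np.ndarray:
    """Mean held-out binomial deviance per grid value, stratified K-fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty tuning grid")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < folds:
        raise ValueError("too few cases in one class to stratify the folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, grid.size))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        model = PenalizedLogit(y[tr], X[tr], penalty=spec)
        for g, lam in enumerate(grid):
            res = model.fit(lam=float(lam))
            p = np.clip(res.predict(X[te]), 1e-12, 1 - 1e-12)
            dev[f, g] = float(np.mean(
                -2.0 * (y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))))
    return dev.mean(axis=0)


def select_lambda_cv(X, y, spec: PenaltySpec, grid, folds: int = 5,
                     seed: int = 0) -> PenaltySpec:
    """lam minimizing mean CV deviance; ties break toward the sparser fit."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 1:
        return replace(spec, lam=float(grid[0]))
    mean_dev = cv_deviance_table(X, y, spec, grid, folds=folds, seed=seed)
    best = mean_dev.min()
    lam = float(grid[np.isclose(mean_dev, best)].max())
    return replace(spec, lam=lam)


def select_lambda_bic(X, y, spec: PenaltySpec, grid) -> PenaltySpec:
    """lam minimizing BIC = 2*nll + log(n)*(support+1); default BAR tuner."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty tuning grid")
    n = y.size
    model = PenalizedLogit(y, X, penalty=spec)
    bics = np.empty(grid.size)
    for g, lam in enumerate(grid):
        res = model.fit(lam=float(lam))
        nll = logistic_neg_loglik(X, y, res.params)
        bics[g] = 2.0 * nll + np.log(n) * (res.support_size + 1)
    lam = float(grid[np.isclose(bics, bics.min())].max())
    return replace(spec, lam=lam)


# ---------------------------------------------------------------------------
# post-selection refit
# ---------------------------------------------------------------------------


class RiskFactorTable:
    """Odds-ratio summary of an unpenalized refit on the selected support."""

    COLUMNS = ("factor", "beta", "wald", "odds_ratio",
               "or_ci_low", "or_ci_high", "p_value")

    def __init__(self, frame: pd.DataFrame, separation: bool = False):
        self.frame = frame
        self.separation = separation

    def to_tsv(self, path=None):
        """Tab-separated table: Factor, beta, Wald, OR(95% CI), P."""
        f = self.frame
        out = pd.DataFrame({
            "Factor": f["factor"],
            "beta": f["beta"].round(4),
            "Wald": f["wald"].round(2),
            "OR(95% CI)": [
                f"{o:.2f}({lo:.2f},{hi:.2f})"
                for o, lo, hi in zip(f["odds_ratio"], f["or_ci_low"], f["or_ci_high"])
            ],
            "P": [f"{p:.2e}" for p in f["p_value"]],
        })
        return out.to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:
        return self.frame.to_string(index=False)


def wald_summary_row(beta: float, se: float) -> dict[str, float]:
    """Wald statistic, odds ratio and 95% CI from a coefficient and its SE."""
    wald = (beta / se) ** 2 if se > 0 else np.inf
    return {
        "beta": beta,
        "wald": wald,
        "odds_ratio": float(np.exp(beta)),
        "or_ci_low": float(np.exp(beta - 1.96 * se)),
        "or_ci_high": float(np.exp(beta + 1.96 * se)),
        "p_value": float(stats.chi2.sf(wald, df=1)),
    }


def refit_and_summarize(X, y, support, feature_names=None) -> RiskFactorTable:
    """Unpenalized logistic refit on the support with Wald/OR/CI per factor.

    Standard errors come from the inverse observed information of the refit;
    separation (diverging coefficients) is flagged rather than masked.
    """
    support = np.asarray(support, dtype=int)
    if support.size == 0:
        raise ValueError("cannot summarize an empty support")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    exog = sm.add_constant(X[:, support], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    separation = (not fit.mle_retvals.get("converged", True)
                  or bool(np.any(np.abs(fit.params) > 1e2))
                  or bool(np.any(~np.isfinite(fit.bse))))
    if separation:
        warnings.warn("possible separation in the refit: coefficients may diverge")
    rows = []
    labels = ["intercept"] + [names[j] for j in support]
    for label, beta, se in zip(labels, fit.params, fit.bse):
        rows.append({"factor": label, **wald_summary_row(float(beta), float(se))})
    return RiskFactorTable(pd.DataFrame(rows, columns=RiskFactorTable.COLUMNS),
                           separation=separation)
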