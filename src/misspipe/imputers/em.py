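"""EM imputation under a multivariate normal working model.

The E-step computes, for every missingness pattern, the conditional mean and
conditional covariance of the missing block given the observed block at the
current (mu, Sigma); the M-step updates (mu, Sigma) from the completed
sufficient statistics, including the conditional-covariance correction.
Missing cells are finally replaced by their conditional means at the
converged parameters.  Binary columns are treated as continuous during the
iterations and rounded at 0.5 on output.

The observed-data log-likelihood is tracked at each iteration; EM guarantees
it is nondecreasing (up to the covariance ridge jitter used for numerical
stability).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np

from ..cohort import MaskedCohort
from .base import ImputedCohort, Imputer, round_binary


@dataclass(frozen=True)
class EmConfig:
    tol: float = 1e-6          # relative change in observed-data log-likelihood
    max_iter: int = 100
    ridge: float = 1e-6        # jitter added to Sigma's diagonal each M-step

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1 or self.ridge < 0:
            raise ValueError("invalid EM configuration")


def _patterns(M: np.ndarray):
    """Group row indices by missingness pattern (observed-column tuple)."""
    groups: dict[bytes, list[int]] = {}
    packed = np.packbits(M, axis=1)
    for i, key in enumerate(map(bytes, packed)):
        groups.setdefault(key, []).append(i)
    for idx in groups.values():
        rows = np.asarray(idx)
        yield rows, M[rows[0]]
    return


class EMImputer(Imputer):
    name = "em"

    def __init__(self, config: EmConfig | None = None):
        self.config = config or EmConfig()

    def config_snapshot(self) -> dict:
        snap = asdict(self.config)
        snap["converged"] = getattr(self, "converged_", None)
        snap["n_iter"] = len(getattr(self, "loglik_trace_", []))
        return snap

    def fit(self, masked: MaskedCohort) -> "EMImputer":
        X, M = masked.X_obs, masked.M
        n, d = X.shape
        if (M.sum(axis=0) == 0).any():
            raise ValueError("every column needs at least one observed value")
        cfg = self.config
        mu = np.nanmean(X, axis=0)
        Xc = np.where(M, X, mu)
        sigma = np.cov(Xc, rowvar=False, bias=True) + cfg.ridge * np.eye(d)
        if d == 1:
            sigma = sigma.reshape(1, 1)

        trace: list[float] = []
        converged = False
        pattern_list = [(rows, obs.copy()) for rows, obs in _patterns(M)]
        for _ in range(cfg.max_iter):
            Xc = np.where(M, X, 0.0)
            cc_sum = np.zeros((d, d))
            loglik = 0.0
            for rows, obs in pattern_list:
                o = np.flatnonzero(obs)
                m = np.flatnonzero(~obs)
                xo = X[np.ix_(rows, o)]
                Soo = sigma[np.ix_(o, o)]
                L = np.linalg.cholesky(Soo)
                dev = xo - mu[o]
                half = np.linalg.solve(L, dev.T)          # L^{-1} (x_o - mu_o)^T
                loglik += (
                    -0.5 * np.sum(half * half)
                    - rows.size * (np.log(np.diag(L)).sum()
                                   + 0.5 * o.size * np.log(2.0 * np.pi))
                )
                if m.size:
                    Smo = sigma[np.ix_(m, o)]
                    W = np.linalg.solve(L.T, np.linalg.solve(L, Smo.T)).T  # Smo Soo^-1
                    cond_mean = mu[m] + dev @ W.T
                    Xc[np.ix_(rows, m)] = cond_mean
                    cond_cov = sigma[np.ix_(m, m)] - W @ Smo.T
                    cc_sum[np.ix_(m, m)] += rows.size * cond_cov
            trace.append(float(loglik))
            mu_new = Xc.mean(axis=0)
            dev_full = Xc - mu_new
            sigma_new = (dev_full.T @ dev_full + cc_sum) / n
            sigma_new += cfg.ridge * np.eye(d)
            mu, sigma = mu_new, sigma_new
            if len(trace) >= 2:
                prev, cur = trace[-2], trace[-1]
                if abs(cur - prev) <= cfg.tol * (abs(prev) + 1.0):
                    converged = True
                    break
        if not converged and M.all():
            converged = True  # complete data: single pass is exact
        if not converged:
            warnings.warn("EM did not converge within max_iter; using best iterate")
        self.mu_, self.sigma_ = mu, sigma
        self.loglik_trace_ = trace
        self.converged_ = converged
        return self

    def _predict_full(self, masked: MaskedCohort) -> np.ndarray:
        X, M = masked.X_obs, masked.M
        mu, sigma = self.mu_, self.sigma_
        pred = np.where(M, X, 0.0)
        for rows, obs in _patterns(M):
            m = np.flatnonzero(~obs)
            if not m.size:
                continue
            o = np.flatnonzero(obs)
            if o.size:
                Soo = sigma[np.ix_(o, o)]
                try:
                    L = np.linalg.cholesky(Soo)
                except np.linalg.LinAlgError:
                    warnings.warn("singular conditional covariance; adding ridge jitter")
                    L = np.linalg.cholesky(Soo + 10 * self.config.ridge * np.eye(o.size))
                Smo = sigma[np.ix_(m, o)]
                W = np.linalg.solve(L.T, np.linalg.solve(L, Smo.T)).T
                pred[np.ix_(rows, m)] = mu[m] + (X[np.ix_(rows, o)] - mu[o]) @ W.T
            else:
                pred[np.ix_(rows, m)] = mu[m]
        return round_binary(pred, masked.schema.is_binary)


def impute_em(masked: MaskedCohort, config: EmConfig | None = None) -> ImputedCohort:
    """EM-impute; the log-likelihood trace rides in ``config_snapshot``."""
    imp = EMImputer(config)
    out = imp.fit(masked).transform(masked)
    out.config_snapshot["loglik_trace"] = list(imp.loglik_trace_)
    return out
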