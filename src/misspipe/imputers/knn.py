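"""K-nearest-neighbour imputation with a Minkowski metric.

Distances between an incomplete row and candidate rows are computed over the
mutually observed coordinates and rescaled by ``(d / #shared)^(1/q)`` so that
rows sharing few coordinates are not spuriously close.  The default metric is
Euclidean (q = 2).  A missing cell is filled with the mean (continuous) or
mode (binary) of its K nearest candidates — rows in the fitted neighbour pool
that observe the target column.  Ties in distance break toward the lower pool
row index.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import minkowski as _scipy_minkowski

from ..cohort import MaskedCohort
from .base import ImputedCohort, Imputer
from .simple import column_fill_values


def minkowski_distance(u: np.ndarray, v: np.ndarray, q: float = 2.0) -> float:
    """Minkowski distance ``(sum |u_k - v_k|^q)^(1/q)`` for q >= 1."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if q < 1:
        raise ValueError("the Minkowski exponent must satisfy q >= 1")
    return float(_scipy_minkowski(u, v, p=q))


@dataclass(frozen=True)
class KnnConfig:
    K: int = 5
    q: float = 2.0

    def __post_init__(self) -> None:
        if self.K < 1 or self.q < 1:
            raise ValueError("require K >= 1 and q >= 1")


class KNNImputer(Imputer):
    name = "knn"

    def __init__(self, config: KnnConfig | None = None):
        self.config = config or KnnConfig()

    def config_snapshot(self) -> dict:
        return asdict(self.config)

    def fit(self, masked: MaskedCohort) -> "KNNImputer":
        self.pool_X_ = masked.X_obs.copy()
        self.pool_M_ = masked.M.copy()
        self.fallback_ = column_fill_values(masked)
        return self

    def _predict_full(self, masked: MaskedCohort) -> np.ndarray:
        K, q = self.config.K, self.config.q
        pool_X, pool_M = self.pool_X_, self.pool_M_
        d = pool_X.shape[1]
        isbin = masked.schema.is_binary
        pool_filled = np.where(pool_M, pool_X, 0.0)
        pred = np.where(masked.M, masked.X_obs, 0.0)

        for i in np.flatnonzero(~masked.M.all(axis=1)):
            mi = masked.M[i]
            xi = np.where(mi, masked.X_obs[i], 0.0)
            shared = pool_M & mi                       # pool_rows x d
            n_shared = shared.sum(axis=1)
            diffs = np.abs(pool_filled - xi) * shared
            with np.errstate(divide="ignore", invalid="ignore"):
                if q == 2.0:
                    dist = np.sqrt((diffs**2).sum(axis=1) * d / n_shared)
                else:
                    dist = ((diffs**q).sum(axis=1) * d / n_shared) ** (1.0 / q)
            dist[n_shared == 0] = np.inf
            for j in np.flatnonzero(~mi):
                cand = np.flatnonzero(pool_M[:, j] & np.isfinite(dist))
                if cand.size == 0:
                    warnings.warn(
                        f"no candidate neighbours observe column "
                        f"{masked.schema.names[j]!r}; falling back to column fill"
                    )
                    pred[i, j] = self.fallback_[j]
                    continue
                order = cand[np.lexsort((cand, dist[cand]))][:K]
                vals = pool_X[order, j]
                if isbin[j]:
                    pred[i, j] = float(vals.mean() >= 0.5)
                else:
                    pred[i, j] = float(vals.mean())
        return pred


def impute_knn(masked: MaskedCohort, config: KnnConfig | None = None) -> ImputedCohort:
    """KNN-impute using the cohort itself as the neighbour pool."""
    return KNNImputer(config).fit_transform(masked)
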