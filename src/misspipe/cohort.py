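"""Synthetic clinical-cohort generation and missingness injection.

The cohorts emulate an incomplete clinical registry: mixed continuous/binary
prognostic factors with latent correlation, a sparse logistic outcome, and a
per-feature missingness profile in which a handful of instrument-derived
measurements are missing for up to ~31% of cases while the overall cell-wise
missing rate stays near 7.7% and roughly three quarters of cases carry at
least one missing value.

Missing cells are represented in memory by ``numpy.nan`` together with an
explicit binary observation mask; on disk they are empty CSV cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

CONTINUOUS = "continuous"
BINARY = "binary"

#: Marginal missing rates of the five worst-observed features in the default
#: profile (instrument-derived pelvic-floor measurements in the motivating
#: registry), highest first.
HIGH_MISSING_RATES = (0.307, 0.306, 0.232, 0.231, 0.228)

#: Default overall cell-wise missing rate and incomplete-row rate of the
#: default profile.
DEFAULT_OVERALL_RATE = 0.0771
DEFAULT_INCOMPLETE_ROW_RATE = 0.7752


# ---------------------------------------------------------------------------
# schema and specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSchema:
    """Names and kinds (continuous vs binary) of the feature columns."""

    names: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.kinds):
            raise ValueError("names and kinds must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        bad = set(self.kinds) - {CONTINUOUS, BINARY}
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")

    @property
    def d(self) -> int:
        return len(self.names)

    @property
    def is_binary(self) -> np.ndarray:
        """Boolean vector, True where the feature is binary."""
        return np.asarray([k == BINARY for k in self.kinds], dtype=bool)

    @classmethod
    def default(cls, d: int = 67, binary_fraction: float = 0.4) -> "FeatureSchema":
        """Schema with ``d`` features, a fixed fraction binary, evenly spread."""
        if not 0.0 <= binary_fraction <= 1.0:
            raise ValueError("binary_fraction must lie in [0, 1]")
        n_bin = int(round(d * binary_fraction))
        kinds = [CONTINUOUS] * d
        if n_bin > 0:
            for idx in np.round(np.linspace(0, d - 1, n_bin)).astype(int):
                kinds[idx] = BINARY
        names = tuple(f"x{j:02d}" for j in range(d))
        return cls(names=names, kinds=tuple(kinds))


#: Coefficient values assigned (in order) to the active features of the
#: default sparse outcome model: mixed signs, magnitudes near 1.
DEFAULT_SUPPORT_BETAS = (1.2, -1.0, 1.0, -0.9, 0.8, -0.8, 1.1, 0.9, -0.7)


@dataclass(frozen=True)
class SyntheticSpec:
    """Data-generating parameters for a complete synthetic cohort."""

    n: int
    schema: FeatureSchema
    beta_true: np.ndarray
    intercept: float
    support_size: int
    corr: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta_true, dtype=float)
        object.__setattr__(self, "beta_true", beta)
        if beta.shape != (self.schema.d,):
            raise ValueError("beta_true length must equal the feature count")
        if int(np.count_nonzero(beta)) != self.support_size:
            raise ValueError("support_size must equal #nonzero entries of beta_true")
        if not 0.0 <= self.corr < 1.0:
            raise ValueError("corr must lie in [0, 1)")
        if self.support_size > self.schema.d:
            raise ValueError("support_size cannot exceed the feature count")
        if self.n < 1:
            raise ValueError("n must be positive")

    @classmethod
    def default(
        cls,
        n: int = 2000,
        d: int = 67,
        support_size: int = 9,
        binary_fraction: float = 0.4,
        corr: float = 0.2,
        seed: int = 0,
    ) -> "SyntheticSpec":
        """Default cohort: ``d`` mixed features, ``support_size`` of them active.

        Active features are spread evenly across the columns and receive the
        fixed coefficients of :data:`DEFAULT_SUPPORT_BETAS` (recycled if
        ``support_size`` differs from its length).  The intercept is chosen to
        offset the mean linear predictor, giving outcome prevalence near 1/2.
        """
        schema = FeatureSchema.default(d=d, binary_fraction=binary_fraction)
        beta = np.zeros(d)
        if support_size > 0:
            support = np.round(np.linspace(0, d - 1, support_size)).astype(int)
            vals = [DEFAULT_SUPPORT_BETAS[i % len(DEFAULT_SUPPORT_BETAS)]
                    for i in range(support_size)]
            beta[support] = vals
        # binary columns have mean ~1/2, continuous columns mean 0
        feature_means = np.where(schema.is_binary, 0.5, 0.0)
        intercept = -float(beta @ feature_means)
        return cls(
            n=n, schema=schema, beta_true=beta, intercept=intercept,
            support_size=support_size, corr=corr, seed=seed,
        )


@dataclass(frozen=True)
class MissingnessSpec:
    """Mechanism and per-feature marginal rates for mask injection.

    mechanism
        ``"mcar"``      — each cell masked independently.
        ``"clustered"`` — row-susceptibility MCAR: a calibrated fraction of
        rows is missing-prone and cells are masked only inside prone rows,
        preserving the marginal per-feature rates while concentrating missing
        values in fewer cases (as clinical registries do).
        ``"mar"``       — cell (i, j) masked with probability
        ``sigmoid(a_j + slope * x[i, driver])``, with ``a_j`` calibrated so
        the marginal rate equals ``per_feature_rate[j]``.
    """

    mechanism: str
    per_feature_rate: np.ndarray
    prone_fraction: float | None = None
    driver_feature: int | None = None
    mar_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = np.asarray(self.per_feature_rate, dtype=float)
        object.__setattr__(self, "per_feature_rate", rates)
        if self.mechanism not in ("mcar", "mar", "clustered"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if rates.ndim != 1:
            raise ValueError("per_feature_rate must be a vector")
        if np.any(rates < 0) or np.any(rates >= 1):
            raise ValueError("per-feature rates must lie in [0, 1)")
        if self.mechanism == "mar":
            if self.driver_feature is None:
                raise ValueError("MAR requires a driver_feature")
            if rates[self.driver_feature] != 0:
                raise ValueError("the MAR driver feature must have rate 0")
        if self.mechanism == "clustered":
            if self.prone_fraction is None:
                raise ValueError("clustered mechanism requires prone_fraction")
            if not rates.max(initial=0.0) <= self.prone_fraction <= 1.0:
                raise ValueError(
                    "prone_fraction must lie in [max rate, 1] so conditional "
                    "rates stay below 1"
                )


def default_missingness_profile(
    d: int = 67,
    overall_rate: float = DEFAULT_OVERALL_RATE,
    incomplete_row_rate: float = DEFAULT_INCOMPLETE_ROW_RATE,
    seed: int = 0,
) -> MissingnessSpec:
    """Row-clustered profile with five high-rate features.

    Features 0-4 get the high marginal rates of :data:`HIGH_MISSING_RATES`;
    the remaining features share a common rate solved so the expected overall
    cell-wise rate equals ``overall_rate``.  The prone-row fraction is solved
    numerically so the expected fraction of rows with at least one missing
    cell equals ``incomplete_row_rate``.
    """
    high = np.asarray(HIGH_MISSING_RATES)
    if d > len(high) and overall_rate * d >= high.sum():
        rest = (overall_rate * d - high.sum()) / (d - len(high))
        rates = np.full(d, rest)
        rates[: len(high)] = high
    else:
        # too few features to carry the high-rate block: fall back to a
        # uniform profile at the requested overall rate
        rates = np.full(d, overall_rate)

    def expected_incomplete(pi: float) -> float:
        return pi * (1.0 - np.prod(1.0 - rates / pi))

    lo = rates.max() + 1e-9
    if expected_incomplete(1.0) < incomplete_row_rate:
        pi = 1.0
    else:
        pi = brentq(lambda p: expected_incomplete(p) - incomplete_row_rate, lo, 1.0)
    return MissingnessSpec(
        mechanism="clustered", per_feature_rate=rates,
        prone_fraction=float(pi), seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort containers
# ---------------------------------------------------------------------------


@dataclass
class CohortMatrix:
    """Complete cohort: feature matrix X, binary outcome y, schema."""

    X: np.ndarray
    y: np.ndarray
    schema: FeatureSchema
    beta_true: np.ndarray | None = None
    intercept: float | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[1] != self.schema.d:
            raise ValueError("X must be n x d with d matching the schema")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows")
        if np.isnan(self.X).any():
            raise ValueError("a complete cohort may not contain missing cells")
        isbin = self.schema.is_binary
        if isbin.any() and not np.isin(self.X[:, isbin], (0.0, 1.0)).all():
            raise ValueError("binary columns must take values in {0, 1}")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class MaskedCohort:
    """Cohort with missing cells: NaN marker in X_obs, mask M (1 = observed)."""

    X_obs: np.ndarray
    M: np.ndarray
    y: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.X_obs = np.asarray(self.X_obs, dtype=float)
        self.M = np.asarray(self.M, dtype=bool)
        self.y = np.asarray(self.y)
        if self.X_obs.shape != self.M.shape:
            raise ValueError("mask shape must match X_obs")
        if self.X_obs.shape[1] != self.schema.d:
            raise ValueError("column count must match the schema")
        if not (np.isnan(self.X_obs) == ~self.M).all():
            raise ValueError("NaN positions and zero-mask positions must coincide")
        if np.isnan(np.asarray(self.y, dtype=float)).any():
            raise ValueError("the outcome may not contain missing values")

    @property
    def n(self) -> int:
        return self.X_obs.shape[0]

    def subset(self, rows: np.ndarray) -> "MaskedCohort":
        """Row-subset view (copies), preserving schema."""
        return MaskedCohort(
            X_obs=self.X_obs[rows].copy(), M=self.M[rows].copy(),
            y=self.y[rows].copy(), schema=self.schema,
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_cohort(spec: SyntheticSpec) -> CohortMatrix:
    """Draw a complete cohort from the documented sampling recipe.

    Recipe (all randomness from ``numpy.random.default_rng(spec.seed)``):

    1. ``E`` — an ``n x d`` matrix of standard normal draws.
    2. AR(1) latent field with parameter ``rho = spec.corr``:
       ``Z[:, 0] = E[:, 0]`` and for j >= 1
       ``Z[:, j] = rho * Z[:, j-1] + sqrt(1 - rho^2) * E[:, j]``
       (standard normal marginals, corr(Z_j, Z_k) = rho^{|j-k|}).
    3. Continuous features are the latent values; binary features threshold
       the latent at 0 (``Z > 0``).
    4. ``y[i] ~ Bernoulli(sigmoid(intercept + X[i] @ beta_true))`` using a
       single uniform draw per row, taken *after* the feature draws.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n, spec.schema.d
    rho = spec.corr
    e = rng.standard_normal((n, d))
    z = np.empty((n, d))
    z[:, 0] = e[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, d):
        z[:, j] = rho * z[:, j - 1] + scale * e[:, j]
    X = z
    isbin = spec.schema.is_binary
    if isbin.any():
        X = X.copy()
        X[:, isbin] = (z[:, isbin] > 0).astype(float)
    eta = spec.intercept + X @ spec.beta_true
    y = (rng.random(n) < expit(eta)).astype(np.int64)
    return CohortMatrix(
        X=X, y=y, schema=spec.schema,
        beta_true=spec.beta_true.copy(), intercept=spec.intercept,
    )


def inject_missingness(cohort: CohortMatrix, mspec: MissingnessSpec) -> MaskedCohort:
    """Mask feature cells of a complete cohort; the outcome is never masked."""
    n, d = cohort.X.shape
    rates = mspec.per_feature_rate
    if rates.shape != (d,):
        raise ValueError("per_feature_rate length must match the cohort width")
    rng = np.random.default_rng(mspec.seed)

    if mspec.mechanism == "mcar":
        miss = rng.random((n, d)) < rates
    elif mspec.mechanism == "clustered":
        pi = float(mspec.prone_fraction)
        prone = rng.random(n) < pi
        cond = rates / pi if pi > 0 else rates
        miss = (rng.random((n, d)) < cond) & prone[:, None]
    else:  # mar
        driver = cohort.X[:, mspec.driver_feature]
        b = mspec.mar_slope
        miss = np.zeros((n, d), dtype=bool)
        u = rng.random((n, d))
        for j in range(d):
            if rates[j] == 0.0:
                continue
            a_j = _solve_mar_intercept(driver, b, rates[j])
            miss[:, j] = u[:, j] < expit(a_j + b * driver)
    M = ~miss
    X_obs = cohort.X.copy()
    X_obs[miss] = np.nan
    return MaskedCohort(X_obs=X_obs, M=M, y=cohort.y.copy(), schema=cohort.schema)


def _solve_mar_intercept(driver: np.ndarray, slope: float, rate: float) -> float:
    """Intercept a s.t. mean_i sigmoid(a + slope * driver_i) == rate."""

    def f(a: float) -> float:
        return float(np.mean(expit(a + slope * driver))) - rate

    lo, hi = -50.0, 50.0
    return brentq(f, lo, hi)


def listwise_delete(masked: MaskedCohort) -> CohortMatrix:
    """Keep only fully observed rows (complete-case analysis), order preserved."""
    complete = masked.M.all(axis=1)
    if not complete.any():
        raise ValueError("listwise deletion removed every row")
    return CohortMatrix(
        X=masked.X_obs[complete].copy(), y=masked.y[complete].copy(),
        schema=masked.schema,
    )


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

OUTCOME_COLUMN = "outcome"


def cohort_to_frame(obj: CohortMatrix | MaskedCohort) -> pd.DataFrame:
    X = obj.X if isinstance(obj, CohortMatrix) else obj.X_obs
    df = pd.DataFrame(X, columns=list(obj.schema.names))
    df[OUTCOME_COLUMN] = np.asarray(obj.y)
    return df


def write_cohort(obj: CohortMatrix | MaskedCohort, path: str | Path) -> None:
    """Write a cohort as CSV (missing = empty cell) plus a JSON schema sidecar."""
    path = Path(path)
    cohort_to_frame(obj).to_csv(path, index=False, na_rep="")
    sidecar = {
        "names": list(obj.schema.names),
        "kinds": list(obj.schema.kinds),
        "outcome": OUTCOME_COLUMN,
    }
    if isinstance(obj, CohortMatrix) and obj.beta_true is not None:
        sidecar["beta_true"] = [float(b) for b in obj.beta_true]
        sidecar["intercept"] = obj.intercept
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_masked(path: str | Path, schema_path: str | Path | None = None) -> MaskedCohort:
    """Read a CSV cohort (empty or NA cells = missing) with its schema sidecar."""
    path = Path(path)
    if schema_path is None:
        schema_path = path.with_suffix(path.suffix + ".schema.json")
    sidecar = json.loads(Path(schema_path).read_text())
    schema = FeatureSchema(names=tuple(sidecar["names"]), kinds=tuple(sidecar["kinds"]))
    df = pd.read_csv(path, na_values=["", "NA"])
    y = df.pop(sidecar.get("outcome", OUTCOME_COLUMN)).to_numpy()
    X_obs = df[list(schema.names)].to_numpy(dtype=float)
    return MaskedCohort(X_obs=X_obs, M=~np.isnan(X_obs), y=y, schema=schema)
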