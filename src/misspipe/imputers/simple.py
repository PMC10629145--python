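"""Mean/mode imputation: observed column mean (continuous) or mode (binary)."""

from __future__ import annotations

import numpy as np

from ..cohort import MaskedCohort
from .base import ImputedCohort, Imputer


def column_fill_values(masked: MaskedCohort) -> np.ndarray:
    """Per-column fill value: observed mean, or observed mode for binary columns.

    A tied binary mode resolves to 1 (mean >= 0.5), keeping the rule
    deterministic.  Raises on a fully missing column.
    """
    obs_counts = masked.M.sum(axis=0)
    if (obs_counts == 0).any():
        j = int(np.argmin(obs_counts))
        raise ValueError(f"column {masked.schema.names[j]!r} has no observed values")
    means = np.nanmean(masked.X_obs, axis=0)
    fill = means.copy()
    isbin = masked.schema.is_binary
    fill[isbin] = (means[isbin] >= 0.5).astype(float)
    return fill


class MeanImputer(Imputer):
    name = "mean"

    def fit(self, masked: MaskedCohort) -> "MeanImputer":
        self.fill_values_ = column_fill_values(masked)
        return self

    def _predict_full(self, masked: MaskedCohort) -> np.ndarray:
        return np.broadcast_to(self.fill_values_, masked.X_obs.shape).copy()


def impute_mean(masked: MaskedCohort) -> ImputedCohort:
    """Fill each missing cell with its column's observed mean/mode."""
    return MeanImputer().fit_transform(masked)
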