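"""Common fit/transform contract for all imputers.

Every imputer is fitted on a (training) masked cohort and can then complete
any cohort with the same schema.  The composition step is shared: observed
cells are copied bit-exactly from the input; only missing cells receive the
imputer's predictions.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..cohort import MaskedCohort


@dataclass
class ImputedCohort:
    """Completed matrix plus provenance."""

    X_hat: np.ndarray
    method: str
    config_snapshot: dict[str, Any]
    M: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.X_hat).any():
            raise ValueError("imputed matrix may not contain missing cells")


class Imputer(ABC):
    """Base class: ``fit`` learns from training data only, ``transform`` completes."""

    name: str = "imputer"

    @abstractmethod
    def fit(self, masked: MaskedCohort) -> "Imputer":
        """Learn imputation parameters from the training cohort."""

    @abstractmethod
    def _predict_full(self, masked: MaskedCohort) -> np.ndarray:
        """Return an n x d matrix of predictions (values at observed cells
        are ignored by the composition step)."""

    def config_snapshot(self) -> dict[str, Any]:
        return {}

    def transform(self, masked: MaskedCohort) -> ImputedCohort:
        pred = self._predict_full(masked)
        X_hat = np.where(masked.M, masked.X_obs, pred)
        if np.isnan(X_hat).any():
            raise RuntimeError(f"{self.name}: predictions left missing cells unfilled")
        return ImputedCohort(
            X_hat=X_hat, method=self.name,
            config_snapshot=self.config_snapshot(), M=masked.M.copy(),
            y=masked.y.copy(),
        )

    def fit_transform(self, masked: MaskedCohort) -> ImputedCohort:
        return self.fit(masked).transform(masked)


def round_binary(pred: np.ndarray, is_binary: np.ndarray) -> np.ndarray:
    """Clip binary-column predictions to [0, 1] and round at 0.5, in place."""
    if is_binary.any():
        b = np.clip(pred[:, is_binary], 0.0, 1.0)
        pred[:, is_binary] = (b >= 0.5).astype(float)
    return pred
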