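"""Classification metrics and imputation-quality scores."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import rankdata

from .cohort import CohortMatrix
from .imputers.base import ImputedCohort


class ConfusionCounts(NamedTuple):
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[ConfusionCounts, float, float]:
    """Confusion counts, accuracy and F1 (F1 = 0 when precision+recall = 0)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction and truth must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    counts = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    accuracy = (tp + tn) / counts.total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return counts, accuracy, f1


def auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties 1/2."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)                     # mid-ranks handle ties at 1/2
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class ImputationError:
    """Masked-cell recovery error against the known complete cohort."""

    rmse: float            # continuous masked cells (nan if none)
    mismatch_rate: float   # binary masked cells   (nan if none)
    n_masked_continuous: int
    n_masked_binary: int


def imputation_error(imputed: ImputedCohort, truth: CohortMatrix) -> ImputationError:
    """RMSE over masked continuous cells and mismatch rate over masked binary cells."""
    if imputed.X_hat.shape != truth.X.shape:
        raise ValueError("imputed and truth shapes differ")
    masked = ~imputed.M
    if not masked.any():
        raise ValueError("no masked cells to score")
    isbin = truth.schema.is_binary
    cont_mask = masked & ~isbin
    bin_mask = masked & isbin
    if cont_mask.any():
        diff = imputed.X_hat[cont_mask] - truth.X[cont_mask]
        rmse = float(np.sqrt(np.mean(diff**2)))
    else:
        rmse = float("nan")
    if bin_mask.any():
        mismatch = float(np.mean(imputed.X_hat[bin_mask] != truth.X[bin_mask]))
    else:
        mismatch = float("nan")
    return ImputationError(
        rmse=rmse, mismatch_rate=mismatch,
        n_masked_continuous=int(cont_mask.sum()),
        n_masked_binary=int(bin_mask.sum()),
    )
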