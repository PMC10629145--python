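"""Repeated-holdout benchmarking of imputer x selector x classifier grids.

Each repeat draws a stratified train/test split, fits the imputer on the
training partition only (no information from test rows enters any imputation
parameter), completes both partitions, optionally selects features on the
imputed training data, trains the classifier and scores the held-out cases.
Cells report the mean and sample standard deviation (n-1) of accuracy, F1
and AUC over repeats.  A ``"listwise"`` pseudo-imputer is the
complete-case-analysis baseline: incomplete rows are dropped from both
partitions and the complete test subset is scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .cohort import MaskedCohort, listwise_delete
from .imputers import (DaeConfig, DAEImputer, EmConfig, EMImputer, GainConfig,
                       GAINImputer, Imputer, KnnConfig, KNNImputer, MeanImputer)
from .metrics import auc, classification_metrics
from .penalized import (PenaltySpec, PenalizedLogit, select_lambda_bic,
                        select_lambda_cv)

# ---------------------------------------------------------------------------
# component registries
# ---------------------------------------------------------------------------


def make_imputer(name: str, seed: int, **overrides) -> Imputer:
    """Fresh imputer instance; trainable ones are seeded per repeat."""
    if name == "mean":
        return MeanImputer()
    if name == "em":
        return EMImputer(EmConfig(**overrides))
    if name == "knn":
        return KNNImputer(KnnConfig(**overrides))
    if name == "dae":
        overrides.setdefault("seed", seed)
        return DAEImputer(DaeConfig(**overrides))
    if name == "gain":
        overrides.setdefault("seed", seed)
        return GAINImputer(GainConfig(**overrides))
    raise ValueError(f"unknown imputer {name!r}")


_DEFAULT_GRID = np.geomspace(0.3, 30.0, 6)


def select_support(name: str, X: np.ndarray, y: np.ndarray, seed: int,
                   grid=None, folds: int = 3) -> np.ndarray:
    """Run a feature selector on (imputed) training data; returns indices."""
    if name in (None, "none"):
        return np.arange(X.shape[1])
    if name == "bar":
        spec = PenaltySpec(family="bar")
        spec = select_lambda_bic(X, y, spec, grid if grid is not None else _DEFAULT_GRID)
    elif name in ("lasso", "scad", "elasticnet"):
        spec = PenaltySpec(family=name)
        spec = select_lambda_cv(X, y, spec,
                                grid if grid is not None else _DEFAULT_GRID / 10.0,
                                folds=folds, seed=seed)
    else:
        raise ValueError(f"unknown selector {name!r}")
    res = PenalizedLogit(y, X, penalty=spec).fit()
    if res.support_size == 0:
        warnings.warn(f"selector {name!r} kept no features; using all")
        return np.arange(X.shape[1])
    return res.support


def _fit_and_score(name: str, Xtr, ytr, Xte, seed: int) -> np.ndarray:
    """Train a classifier and return held-out event scores (probabilities or
    decision values)."""
    if name == "logistic":
        clf = LogisticRegression(C=np.inf, max_iter=2000)
        return clf.fit(Xtr, ytr).predict_proba(Xte)[:, 1]
    if name == "rf":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
        return clf.fit(Xtr, ytr).predict_proba(Xte)[:, 1]
    if name == "svc":
        clf = SVC(kernel="rbf", random_state=seed)
        from scipy.special import expit
        return expit(clf.fit(Xtr, ytr).decision_function(Xte))
    if name == "gboost":
        clf = HistGradientBoostingClassifier(random_state=seed)
        return clf.fit(Xtr, ytr).predict_proba(Xte)[:, 1]
    if name in ("lasso-lr", "scad-lr", "enet-lr"):
        family = {"lasso-lr": "lasso", "scad-lr": "scad",
                  "enet-lr": "elasticnet"}[name]
        spec = select_lambda_cv(Xtr, ytr, PenaltySpec(family=family),
                                _DEFAULT_GRID / 10.0, folds=3, seed=seed)
        res = PenalizedLogit(ytr, Xtr, penalty=spec).fit()
        return res.predict(Xte)
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------

METRICS = ("accuracy", "f1", "auc")


@dataclass
class CellStats:
    """Aggregates for one (imputer, selector, classifier) combination."""

    mean: dict[str, float]
    sd: dict[str, float]
    support_sizes: list[int]
    n_ok: int
    n_fail: int
    flags: list[str] = field(default_factory=list)


@dataclass
class EvalReport:
    cells: dict[tuple[str, str, str], CellStats]
    R: int
    master_seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (imp, sel, clf), cell in self.cells.items():
            row: dict[str, Any] = {"imputer": imp, "selector": sel, "classifier": clf}
            for m in METRICS:
                row[f"{m}_mean"] = cell.mean[m]
                row[f"{m}_sd"] = cell.sd[m]
            row["mean_support"] = (float(np.mean(cell.support_sizes))
                                   if cell.support_sizes else np.nan)
            row["n_fail"] = cell.n_fail
            row["flags"] = ";".join(cell.flags)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path=None):
        return self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = {
            "R": self.R,
            "master_seed": self.master_seed,
            "cells": [
                {"imputer": k[0], "selector": k[1], "classifier": k[2],
                 "mean": c.mean, "sd": c.sd,
                 "support_sizes": c.support_sizes,
                 "n_ok": c.n_ok, "n_fail": c.n_fail, "flags": c.flags}
                for k, c in self.cells.items()
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# the benchmark loop
# ---------------------------------------------------------------------------


def repeat_seeds(master_seed: int, R: int) -> list[int]:
    """Deterministic per-repeat seeds spawned from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(R)]


def _run_cell_repeat(masked: MaskedCohort, imputer_name: str,
                     imputer_overrides: dict, selector: str, classifier: str,
                     seed: int, split_frac: float) -> tuple[dict[str, float], int]:
    idx = np.arange(masked.n)
    tr, te = train_test_split(idx, test_size=split_frac, stratify=masked.y,
                              random_state=seed)
    train, test = masked.subset(tr), masked.subset(te)

    if imputer_name == "listwise":
        train_cm = listwise_delete(train)
        Xtr, ytr = train_cm.X, train_cm.y
        complete_te = test.M.all(axis=1)
        if not complete_te.any():
            raise RuntimeError("no complete test rows for the listwise baseline")
        Xte = test.X_obs[complete_te]
        yte = test.y[complete_te]
    else:
        imp = make_imputer(imputer_name, seed=seed, **imputer_overrides)
        imp.fit(train)
        Xtr, ytr = imp.transform(train).X_hat, train.y
        Xte, yte = imp.transform(test).X_hat, test.y

    keep = select_support(selector, Xtr, ytr, seed=seed)
    scores = _fit_and_score(classifier, Xtr[:, keep], ytr, Xte[:, keep], seed=seed)
    pred = (scores >= 0.5).astype(int)
    _, acc, f1 = classification_metrics(yte, pred)
    out = {"accuracy": acc, "f1": f1, "auc": auc(yte, scores)}
    return out, int(keep.size)


def run_benchmark(
    masked: MaskedCohort,
    imputers: list[str] | dict[str, dict],
    selectors: list[str],
    classifiers: list[str],
    R: int = 100,
    split_frac: float = 0.2,
    master_seed: int = 0,
) -> EvalReport:
    """Run the full repeated-holdout grid and aggregate mean(SD) per cell.

    ``imputers`` is a list of names (``mean``, ``em``, ``knn``, ``dae``,
    ``gain``, ``listwise``) or a mapping name -> config overrides.  A cell
    failing on more than 10% of repeats is flagged, not dropped.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    if len(np.unique(masked.y)) < 2:
        raise ValueError("benchmark needs both outcome classes")
    if isinstance(imputers, dict):
        imp_items = list(imputers.items())
    else:
        imp_items = [(name, {}) for name in imputers]
    seeds = repeat_seeds(master_seed, R)

    cells: dict[tuple[str, str, str], CellStats] = {}
    for imp_name, overrides in imp_items:
        for sel in selectors:
            for clf in classifiers:
                per_metric: dict[str, list[float]] = {m: [] for m in METRICS}
                supports: list[int] = []
                n_fail = 0
                for seed in seeds:
                    try:
                        vals, supp = _run_cell_repeat(
                            masked, imp_name, overrides, sel, clf,
                            seed, split_frac)
                    except Exception as exc:  # noqa: BLE001 - cell-level isolation
                        warnings.warn(
                            f"repeat failed for ({imp_name},{sel},{clf}): {exc}")
                        n_fail += 1
                        continue
                    for m in METRICS:
                        per_metric[m].append(vals[m])
                    supports.append(supp)
                flags = []
                n_ok = len(per_metric["accuracy"])
                if R == 1:
                    flags.append("single_repeat")
                if n_fail > 0.1 * R:
                    flags.append("high_failure_rate")
                mean = {m: (float(np.mean(v)) if v else float("nan"))
                        for m, v in per_metric.items()}
                sd = {m: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
                      for m, v in per_metric.items()}
                cells[(imp_name, sel, clf)] = CellStats(
                    mean=mean, sd=sd, support_sizes=supports,
                    n_ok=n_ok, n_fail=n_fail, flags=flags)
    return EvalReport(cells=cells, R=R, master_seed=master_seed)
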