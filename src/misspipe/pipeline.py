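"""Config-driven orchestration: simulate -> impute -> select -> classify -> report.

A run is described by a :class:`RunConfig` (YAML on disk).  ``run_pipeline``
executes the stages in order, writes every artifact (imputed matrices with
provenance, selection results, risk-factor table, evaluation report) plus a
manifest capturing the config snapshot, derived seeds, package version and
per-stage wall time.  Identical config + master seed reproduces every numeric
output bit-exactly; the manifest alone suffices to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .benchmark import make_imputer, run_benchmark, select_support
from .cohort import (MissingnessSpec, SyntheticSpec, default_missingness_profile,
                     generate_cohort, inject_missingness, read_masked,
                     write_cohort)
from .penalized import PenaltySpec, PenalizedLogit, refit_and_summarize

log = logging.getLogger("misspipe")

STAGE_ORDER = ("simulate", "impute", "select", "classify")


@dataclass
class RunConfig:
    """Flat description of a full pipeline run."""

    input_csv: str | None = None            # existing cohort, or None to simulate
    n: int = 1000
    d: int = 67
    support_size: int = 9
    binary_fraction: float = 0.4
    corr: float = 0.2
    missingness: str = "default"            # "default", "mcar", "mar", "none"
    overall_rate: float = 0.0771
    imputers: dict[str, dict] = field(default_factory=lambda: {"mean": {}})
    selectors: list[str] = field(default_factory=lambda: ["lasso", "bar"])
    classifiers: list[str] = field(default_factory=lambda: ["logistic"])
    include_listwise: bool = True
    R: int = 10
    split_frac: float = 0.2
    master_seed: int = 0
    out_dir: str = "misspipe_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def validate(self) -> list[str]:
        """Itemized validation errors; empty list means the config is runnable."""
        errors = []
        known_imp = {"mean", "em", "knn", "dae", "gain"}
        unknown = set(self.imputers) - known_imp
        if unknown:
            errors.append(f"unknown imputers: {sorted(unknown)}")
        if not self.imputers and not self.include_listwise:
            errors.append("enable at least one imputer or the listwise baseline")
        for sel in self.selectors:
            if sel not in ("none", "lasso", "elasticnet", "scad", "bar"):
                errors.append(f"unknown selector: {sel}")
        for clf in self.classifiers:
            if clf not in ("logistic", "rf", "svc", "gboost",
                           "lasso-lr", "scad-lr", "enet-lr"):
                errors.append(f"unknown classifier: {clf}")
        if self.R < 1:
            errors.append("R must be >= 1")
        if not 0 < self.split_frac < 1:
            errors.append("split_frac must lie in (0, 1)")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            errors.append(f"input_csv not found: {self.input_csv}")
        if self.missingness not in ("default", "mcar", "mar", "none"):
            errors.append(f"unknown missingness mode: {self.missingness}")
        return errors


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Independent per-stage seeds spawned deterministically from the master."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGE_ORDER))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(STAGE_ORDER, children)}


def _build_masked(config: RunConfig, seeds: dict[str, int]):
    if config.input_csv is not None:
        return read_masked(config.input_csv), None
    spec = SyntheticSpec.default(
        n=config.n, d=config.d, support_size=config.support_size,
        binary_fraction=config.binary_fraction, corr=config.corr,
        seed=seeds["simulate"],
    )
    cohort = generate_cohort(spec)
    if config.missingness == "none":
        mspec = MissingnessSpec(mechanism="mcar",
                                per_feature_rate=np.zeros(config.d),
                                seed=seeds["simulate"] + 1)
    elif config.missingness == "default":
        mspec = default_missingness_profile(d=config.d,
                                            overall_rate=config.overall_rate,
                                            seed=seeds["simulate"] + 1)
    elif config.missingness == "mcar":
        mspec = MissingnessSpec(
            mechanism="mcar",
            per_feature_rate=np.full(config.d, config.overall_rate),
            seed=seeds["simulate"] + 1)
    else:  # mar: last feature drives, itself always observed
        rates = np.full(config.d, config.overall_rate)
        rates[-1] = 0.0
        mspec = MissingnessSpec(mechanism="mar", per_feature_rate=rates,
                                driver_feature=config.d - 1,
                                seed=seeds["simulate"] + 1)
    return inject_missingness(cohort, mspec), cohort


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict[str, Any]:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    if dry_run:
        log.info("dry run: config is valid, no outputs written")
        return {"dry_run": True, "config": config.to_dict(), "errors": []}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.master_seed)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "stage_order": [],
        "stage_seconds": {},
        "failures": [],
    }

    def stage(name):
        manifest["stage_order"].append(name)
        log.info("stage %s", name)
        return time.perf_counter()

    # --- simulate / load -------------------------------------------------
    t0 = stage("simulate")
    masked, truth = _build_masked(config, seeds)
    write_cohort(masked, out / "cohort_masked.csv")
    if truth is not None:
        write_cohort(truth, out / "cohort_complete.csv")
    manifest["stage_seconds"]["simulate"] = time.perf_counter() - t0

    # --- impute ----------------------------------------------------------
    t0 = stage("impute")
    imputed_matrices = {}
    for name, overrides in config.imputers.items():
        try:
            imp = make_imputer(name, seed=seeds["impute"], **overrides)
            res = imp.fit_transform(masked)
            imputed_matrices[name] = res
            df = np.c_[res.X_hat, masked.y]
            header = ",".join(list(masked.schema.names) + ["outcome"])
            np.savetxt(out / f"imputed_{name}.csv", df, delimiter=",",
                       header=header, comments="", fmt="%.10g")
            (out / f"imputed_{name}.provenance.json").write_text(
                json.dumps({"method": res.method,
                            "config": _jsonable(res.config_snapshot),
                            "seed": seeds["impute"]}, indent=2))
        except Exception as exc:  # noqa: BLE001 - partial failure is recorded
            log.warning("imputer %s failed: %s", name, exc)
            manifest["failures"].append({"stage": "impute", "cell": name,
                                         "error": str(exc)})
    manifest["stage_seconds"]["impute"] = time.perf_counter() - t0

    # --- select ----------------------------------------------------------
    t0 = stage("select")
    selections: dict[str, Any] = {}
    if imputed_matrices and config.selectors:
        ref_name = next(iter(imputed_matrices))
        X = imputed_matrices[ref_name].X_hat
        y = masked.y
        for sel in config.selectors:
            if sel == "none":
                continue
            try:
                keep = select_support(sel, X, y, seed=seeds["select"])
                selections[sel] = keep.tolist()
                table = refit_and_summarize(X, y, keep,
                                            feature_names=list(masked.schema.names))
                table.to_tsv(out / f"risk_factors_{sel}.tsv")
            except Exception as exc:  # noqa: BLE001
                log.warning("selector %s failed: %s", sel, exc)
                manifest["failures"].append({"stage": "select", "cell": sel,
                                             "error": str(exc)})
        (out / "selection_results.json").write_text(
            json.dumps({"imputer": ref_name, "supports": selections}, indent=2))
    manifest["stage_seconds"]["select"] = time.perf_counter() - t0

    # --- classify / evaluate --------------------------------------------
    t0 = stage("classify")
    imputer_grid = dict(config.imputers)
    if config.include_listwise:
        imputer_grid["listwise"] = {}
    report = run_benchmark(
        masked, imputer_grid, config.selectors, config.classifiers,
        R=config.R, split_frac=config.split_frac,
        master_seed=seeds["classify"])
    report.to_tsv(out / "eval_report.tsv")
    report.to_json(out / "eval_report.json")
    manifest["stage_seconds"]["classify"] = time.perf_counter() - t0

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
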