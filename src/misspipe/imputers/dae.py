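"""Denoising-autoencoder imputation.

A symmetric fully connected network — encoder widths (d+t, d+2t, d+3t),
decoder widths (d+3t, d+2t, d+t), output width d, with layer-width increment
t (default 7) — is trained to reconstruct the observed cells from an input in
which every missing cell holds its column-mean placeholder.  Continuous
features are min-max scaled to [0, 1] from training observations; the loss is
squared error over observed cells only.  After training, missing cells take
the network's outputs (binary columns rounded at 0.5); observed cells are
restored bit-exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from ..cohort import MaskedCohort
from ._nn import MLP, Adam, MinMaxScaler01
from .base import ImputedCohort, Imputer, round_binary


@dataclass(frozen=True)
class DaeConfig:
    theta: int = 7               # layer-width increment
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 64
    corruption: float = 0.2      # extra observed inputs hidden per batch (denoising)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid DAE configuration")
        if not 0.0 <= self.corruption < 1.0:
            raise ValueError("corruption must lie in [0, 1)")


def dae_widths(d: int, theta: int) -> list[int]:
    """Layer widths input→output: encoder d+t, d+2t, d+3t; mirrored decoder."""
    t = theta
    return [d, d + t, d + 2 * t, d + 3 * t, d + 2 * t, d + t, d]


class DAEImputer(Imputer):
    name = "dae"

    def __init__(self, config: DaeConfig | None = None):
        self.config = config or DaeConfig()

    def config_snapshot(self) -> dict:
        snap = asdict(self.config)
        snap["loss_trace"] = list(getattr(self, "loss_trace_", []))
        return snap

    def fit(self, masked: MaskedCohort) -> "DAEImputer":
        cfg = self.config
        X, M = masked.X_obs, masked.M
        n, d = X.shape
        if n < cfg.batch_size and not M.all():
            raise ValueError("need at least batch_size rows to train")
        rng = np.random.default_rng(cfg.seed)
        self.scaler_ = MinMaxScaler01().fit(X, M)
        Xs = np.where(M, self.scaler_.transform(X), np.nan)
        self.placeholders_ = np.nanmean(Xs, axis=0) if not M.all() \
            else np.zeros(d)
        self.net_ = MLP(dae_widths(d, cfg.theta), out="linear", rng=rng)
        # warm start at the mean-imputation solution: with the output bias at
        # the column means, training can only improve on the mean baseline
        self.net_.b[-1][:] = self.placeholders_
        self.loss_trace_ = []
        if M.all():
            return self  # nothing to learn from: identity restoration applies
        filled = np.where(M, Xs, self.placeholders_)
        opt = Adam(self.net_.params, lr=cfg.learning_rate)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                target, mb = filled[idx], M[idx]
                xb = target
                if cfg.corruption > 0:
                    # denoising: hide extra observed inputs behind their
                    # placeholders; the loss still scores them against the
                    # uncorrupted values, so the net must learn to predict
                    # cells from the other features
                    drop = (rng.random(target.shape) < cfg.corruption) & mb
                    xb = np.where(drop, self.placeholders_, target)
                out = self.net_.forward(xb)
                resid = (out - target) * mb
                n_obs = max(int(mb.sum()), 1)
                loss = float((resid**2).sum()) / n_obs
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"DAE training diverged (non-finite loss); "
                        f"trace so far: {self.loss_trace_[-5:]}"
                    )
                grads, _ = self.net_.backward(2.0 * resid / n_obs)
                opt.step(grads)
                epoch_loss += loss * idx.size
            self.loss_trace_.append(epoch_loss / n)
        return self

    def _predict_full(self, masked: MaskedCohort) -> np.ndarray:
        X, M = masked.X_obs, masked.M
        Xs = np.where(M, self.scaler_.transform(X), 0.0)
        filled = np.where(M, Xs, self.placeholders_)
        out = np.clip(self.net_.forward(filled), 0.0, 1.0)
        pred = self.scaler_.inverse(out)
        return round_binary(pred, masked.schema.is_binary)


def impute_dae(masked: MaskedCohort, config: DaeConfig | None = None) -> ImputedCohort:
    """Train a denoising autoencoder on the cohort and complete it."""
    return DAEImputer(config).fit_transform(masked)
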