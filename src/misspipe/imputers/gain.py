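"""Generative-adversarial imputation (GAIN).

A generator network sees the observed part of each case (missing slots filled
with small uniform noise) together with the mask, and proposes a completed
vector; a discriminator sees the composed vector ``X_hat = M*X + (1-M)*Xbar``
together with a hint vector and predicts, per coordinate, the probability
that the coordinate was genuinely observed.  The hint reveals the true mask
at every coordinate except one randomly chosen slot per case (set to 0.5),
so the discriminator's real task concentrates on the hidden slot; a
Bernoulli-hint variant hides several slots per case.  Training alternates
mini-batch adversarial updates — the generator's adversarial loss covers the
hidden slots, where fooling is possible — and the generator additionally
pays a reconstruction penalty (weight ``alpha``) on observed cells: squared
error for continuous features, cross-entropy for binary ones.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import NamedTuple

import numpy as np

from ..cohort import FeatureSchema, MaskedCohort
from ._nn import MLP, Adam, MinMaxScaler01
from .base import ImputedCohort, Imputer, round_binary

_EPS = 1e-8


def make_hint(m_row: np.ndarray, k: int) -> np.ndarray:
    """Hint vector ``H = B*M + 0.5*(1-B)`` with ``B`` zero only at slot ``k``.

    ``k`` is a 0-based coordinate index; H equals the mask everywhere except
    H[k] = 0.5.
    """
    m_row = np.asarray(m_row, dtype=float)
    d = m_row.shape[0]
    if not 0 <= k < d:
        raise ValueError(f"hint coordinate {k} out of range for d={d}")
    b = np.ones(d)
    b[k] = 0.0
    return b * m_row + 0.5 * (1.0 - b)


class GainLosses(NamedTuple):
    L_D: float          # discriminator log-likelihood over hidden slots (Eq-style sum)
    L_G: float          # generator's adversarial loss, nonnegative
    L_M: float          # reconstruction loss over observed cells, nonnegative
    g_objective: float  # L_G + alpha * L_M


def gain_losses(
    m: np.ndarray,
    m_hat: np.ndarray,
    b: np.ndarray,
    x: np.ndarray,
    x_prime: np.ndarray,
    schema: FeatureSchema,
    alpha: float,
) -> GainLosses:
    """Per-sample GAIN losses.

    ``m`` true mask, ``m_hat`` discriminator probabilities, ``b`` the hint
    selector (0 marks the hidden slot(s)), ``x`` the true vector, ``x_prime``
    the generator output.  ``L_D`` sums ``(1-m)log(1-m_hat) + m log(m_hat)``
    over hidden slots (the discriminator maximizes it / minimizes its
    negative); ``L_G = -sum (1-m) log(m_hat)`` over hidden slots; ``L_M``
    sums, over observed slots, squared error for continuous features and
    ``-x log(x_prime)`` for binary ones.
    """
    m = np.asarray(m, dtype=float)
    mh = np.clip(np.asarray(m_hat, dtype=float), _EPS, 1.0 - _EPS)
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    xp = np.asarray(x_prime, dtype=float)
    hidden = b == 0
    L_D = float(np.sum(((1 - m) * np.log(1 - mh) + m * np.log(mh))[hidden]))
    L_G = float(-np.sum(((1 - m) * np.log(mh))[hidden]))
    isbin = schema.is_binary
    xp_safe = np.clip(xp, _EPS, None)
    per = np.where(isbin, -x * np.log(xp_safe), (xp - x) ** 2)
    L_M = float(np.sum(m * per))
    return GainLosses(L_D=L_D, L_G=L_G, L_M=L_M, g_objective=L_G + alpha * L_M)


@dataclass(frozen=True)
class GainConfig:
    alpha: float = 100.0         # reconstruction weight in the generator objective
    batch_g: int = 128
    batch_d: int = 128
    iterations: int = 10_000
    learning_rate: float = 1e-3
    noise_scale: float = 0.01    # missing slots seeded with U[0, noise_scale)
    hidden_width: int | None = None   # None -> d
    hint_mechanism: str = "single"    # "single" slot at 0.5, or "bernoulli"
    hint_rate: float = 0.9            # reveal probability for the bernoulli variant
    loss_all_coords: bool = True      # train D on every coordinate, not only hidden
    activation: str = "relu"          # hidden activation of both networks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.batch_g < 1 or self.batch_d < 1:
            raise ValueError("invalid GAIN configuration")
        if self.hint_mechanism not in ("single", "bernoulli"):
            raise ValueError("hint_mechanism must be 'single' or 'bernoulli'")


class GAINImputer(Imputer):
    name = "gain"

    def __init__(self, config: GainConfig | None = None):
        self.config = config or GainConfig()

    def config_snapshot(self) -> dict:
        snap = asdict(self.config)
        snap["loss_trace"] = list(getattr(self, "loss_trace_", []))[-50:]
        return snap

    # -- training ----------------------------------------------------------

    def _draw_b(self, rng: np.random.Generator, nb: int, d: int) -> np.ndarray:
        if self.config.hint_mechanism == "single":
            b = np.ones((nb, d))
            b[np.arange(nb), rng.integers(0, d, size=nb)] = 0.0
        else:
            b = (rng.random((nb, d)) < self.config.hint_rate).astype(float)
        return b

    def fit(self, masked: MaskedCohort) -> "GAINImputer":
        cfg = self.config
        X, M = masked.X_obs, masked.M
        n, d = X.shape
        rng = np.random.default_rng(cfg.seed)
        self.scaler_ = MinMaxScaler01().fit(X, M)
        h = cfg.hidden_width or d
        self.G_ = MLP([2 * d, h, h, d], out="sigmoid", rng=rng,
                      hidden=cfg.activation)
        self.D_ = MLP([2 * d, h, h, d], out="sigmoid", rng=rng,
                      hidden=cfg.activation)
        self.loss_trace_ = []
        if M.all():
            return self  # nothing to impute: skip adversarial training
        if n < max(cfg.batch_g, cfg.batch_d):
            raise ValueError("need at least max(batch_g, batch_d) rows to train")
        Xs = np.where(M, self.scaler_.transform(X), 0.0)
        # warm start the generator's output bias at the (scaled) column
        # means, so untrained imputations begin at the mean baseline
        col_means = np.nansum(Xs * M, axis=0) / np.maximum(M.sum(axis=0), 1)
        self.G_.b[-1][:] = np.log(np.clip(col_means, 1e-3, 1 - 1e-3)
                                  / (1 - np.clip(col_means, 1e-3, 1 - 1e-3)))
        Mf = M.astype(float)
        opt_d = Adam(self.D_.params, lr=cfg.learning_rate)
        opt_g = Adam(self.G_.params, lr=cfg.learning_rate)
        isbin = masked.schema.is_binary

        def gen_forward(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            xb, mb = Xs[idx], Mf[idx]
            z = rng.uniform(0.0, cfg.noise_scale, size=xb.shape)
            x_tilde = mb * xb + (1.0 - mb) * z
            g_out = self.G_.forward(np.concatenate([x_tilde, mb], axis=1))
            x_hat = mb * xb + (1.0 - mb) * g_out
            return xb, mb, g_out, x_hat

        for it in range(cfg.iterations):
            # --- discriminator step
            idx = rng.choice(n, size=cfg.batch_d, replace=False)
            xb, mb, _, x_hat = gen_forward(idx)
            bb = self._draw_b(rng, cfg.batch_d, d)
            hint = bb * mb + 0.5 * (1.0 - bb)
            m_hat = self.D_.forward(np.concatenate([x_hat, hint], axis=1))
            mh = np.clip(m_hat, _EPS, 1.0 - _EPS)
            active = np.ones_like(mh, dtype=bool) if cfg.loss_all_coords else bb == 0
            d_loss = -np.sum((mb * np.log(mh) + (1 - mb) * np.log(1 - mh))[active])
            d_loss /= cfg.batch_d
            d_out = np.where(active, -(mb / mh - (1 - mb) / (1 - mh)), 0.0)
            grads, _ = self.D_.backward(d_out / cfg.batch_d)
            opt_d.step(grads)

            # --- generator step
            idx = rng.choice(n, size=cfg.batch_g, replace=False)
            xb, mb, g_out, x_hat = gen_forward(idx)
            bb = self._draw_b(rng, cfg.batch_g, d)
            hint = bb * mb + 0.5 * (1.0 - bb)
            m_hat = self.D_.forward(np.concatenate([x_hat, hint], axis=1))
            mh = np.clip(m_hat, _EPS, 1.0 - _EPS)
            # the generator can only fool the discriminator at hidden slots
            # (b = 0), where the hint left the mask ambiguous; elsewhere the
            # discriminator reads the mask off the hint and the adversarial
            # gradient is pure noise
            hidden = bb == 0
            g_adv = -np.sum(((1 - mb) * np.log(mh))[hidden]) / cfg.batch_g
            d_mhat = np.where(hidden, -(1 - mb) / mh, 0.0) / cfg.batch_g
            _, d_in = self.D_.backward(d_mhat)
            d_gout = d_in[:, :d] * (1.0 - mb)          # through x_hat composition
            n_obs = max(int(mb.sum()), 1)
            g_safe = np.clip(g_out, _EPS, None)
            rec = np.where(isbin, -xb * np.log(g_safe), (g_out - xb) ** 2)
            l_m = float(np.sum(mb * rec)) / n_obs
            d_rec = np.where(isbin, -xb / g_safe, 2.0 * (g_out - xb)) * mb / n_obs
            grads, _ = self.G_.backward(d_gout + cfg.alpha * d_rec)
            opt_g.step(grads)
            total = g_adv + cfg.alpha * l_m
            if not np.isfinite(total) or not np.isfinite(d_loss):
                raise RuntimeError(
                    f"GAIN training diverged at iteration {it}; "
                    f"recent losses: {self.loss_trace_[-5:]}"
                )
            self.loss_trace_.append((float(d_loss), float(total)))
        return self

    def _predict_full(self, masked: MaskedCohort) -> np.ndarray:
        X, M = masked.X_obs, masked.M
        Xs = np.where(M, self.scaler_.transform(X), 0.0)
        Mf = M.astype(float)
        rng = np.random.default_rng(self.config.seed + 1)
        z = rng.uniform(0.0, self.config.noise_scale, size=Xs.shape)
        x_tilde = Mf * Xs + (1.0 - Mf) * z
        g_out = self.G_.forward(np.concatenate([x_tilde, Mf], axis=1))
        pred = self.scaler_.inverse(g_out)
        return round_binary(pred, masked.schema.is_binary)


def impute_gain(masked: MaskedCohort, config: GainConfig | None = None) -> ImputedCohort:
    """Adversarially impute the cohort; observed cells are exactly preserved."""
    return GAINImputer(config).fit_transform(masked)
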