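"""Minimal dense networks and an Adam optimizer on numpy.

Just enough machinery for the reconstruction and adversarial imputers: fully
connected layers, tanh or relu hidden activations, linear or sigmoid outputs, exact
reverse-mode gradients (including the gradient with respect to the input,
needed to train a generator through a frozen discriminator).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class MLP:
    """Fully connected net: 'tanh' or 'relu' hidden layers, 'linear' or
    'sigmoid' output."""

    def __init__(self, widths: list[int], out: str, rng: np.random.Generator,
                 hidden: str = "tanh"):
        if out not in ("linear", "sigmoid"):
            raise ValueError("out must be 'linear' or 'sigmoid'")
        if hidden not in ("tanh", "relu"):
            raise ValueError("hidden must be 'tanh' or 'relu'")
        self.out = out
        self.hidden = hidden
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Forward pass; caches activations for :meth:`backward`."""
        acts = [X]
        h = X
        last = len(self.W) - 1
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if k < last:
                h = np.tanh(z) if self.hidden == "tanh" else np.maximum(z, 0.0)
            elif self.out == "sigmoid":
                h = expit(z)
            else:
                h = z
            acts.append(h)
        self._acts = acts
        return h

    def backward(self, d_out: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients of a scalar loss given dL/d(output).

        Returns (gradients aligned with :attr:`params`, dL/d(input)).
        """
        acts = self._acts
        last = len(self.W) - 1
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        delta = d_out
        for k in range(last, -1, -1):
            h_out = acts[k + 1]
            if k < last:
                if self.hidden == "tanh":
                    delta = delta * (1.0 - h_out * h_out)
                else:
                    delta = delta * (h_out > 0)
            elif self.out == "sigmoid":
                delta = delta * h_out * (1.0 - h_out)
            gW[k] = acts[k].T @ delta
            gb[k] = delta.sum(axis=0)
            delta = delta @ self.W[k].T
        return gW + gb, delta


class Adam:
    """Adaptive-moment gradient descent over a fixed list of arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class MinMaxScaler01:
    """Column-wise min-max scaling to [0, 1] from observed training cells only."""

    def fit(self, X_obs: np.ndarray, M: np.ndarray) -> "MinMaxScaler01":
        Xm = np.where(M, X_obs, np.nan)
        self.lo_ = np.nanmin(Xm, axis=0)
        hi = np.nanmax(Xm, axis=0)
        span = hi - self.lo_
        self.span_ = np.where(span > 0, span, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.lo_) / self.span_

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.span_ + self.lo_
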