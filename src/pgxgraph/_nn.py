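"""Minimal dense neural-network primitives: activations, loss, Adam.

The models in this package are small (graphs with hundreds of nodes, tens of
labels), so the forward/backward passes are written directly against NumPy;
each estimator owns its parameter dictionary and supplies analytic gradients.
"""

from __future__ import annotations

import numpy as np

EPS_PROB = 1e-7  # probability clip inside the loss, avoids log(0)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Multilabel binary cross-entropy: sum over labels, mean over samples.

    ``loss = -(1/n) * sum_i sum_j [ y_ij log(y^_ij) + (1-y_ij) log(1-y^_ij) ]``

    Predictions are clipped to [1e-7, 1-1e-7] before the logs.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs y_hat {y_hat.shape}")
    p = np.clip(y_hat, EPS_PROB, 1.0 - EPS_PROB)
    n = y.shape[0] if y.ndim > 1 else len(np.atleast_1d(y))
    total = np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p))
    return float(-total / max(n, 1))


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
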