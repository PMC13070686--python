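"""Minimal dense-network building blocks: layers, softplus, and AdamW.

These back the feed-forward prediction head and the optimizer; the KAN layers
live in :mod:`dualbind.kan`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def softplus(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable log(1 + exp(x))."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30.0))))


def softplus_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Inverse of softplus; y must be positive."""
    y = np.asarray(y, dtype=np.float64)
    return np.where(y > 30, y, np.log(np.expm1(np.maximum(np.minimum(y, 30.0), 1e-12))))


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class DenseLayer:
    """Affine layer with optional tanh activation."""

    def __init__(self, in_width: int, out_width: int, activation: str,
                 rng: np.random.Generator):
        if activation not in ("tanh", "identity"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.weight = rng.standard_normal((out_width, in_width)) / np.sqrt(in_width)
        self.bias = np.zeros(out_width)
        self.grads: dict[str, np.ndarray] = {}
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.weight.T + self.bias
        y = np.tanh(z) if self.activation == "tanh" else z
        self._cache = (x, y)
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, y = self._cache
        gz = grad_out * (1.0 - y**2) if self.activation == "tanh" else grad_out
        self.grads["weight"] = self.grads.get("weight", 0) + gz.T @ x
        self.grads["bias"] = self.grads.get("bias", 0) + gz.sum(axis=0)
        return gz @ self.weight

    def params(self) -> dict[str, np.ndarray]:
        return {"weight": self.weight, "bias": self.bias}

    def zero_grads(self) -> None:
        self.grads = {}


class MLP:
    """Feed-forward network: tanh hidden layers, linear output."""

    def __init__(self, widths: Sequence[int], rng: np.random.Generator):
        if len(widths) < 2:
            raise ValueError("MLP needs at least input and output widths")
        self.layers = []
        for i, (a, b) in enumerate(zip(widths, widths[1:])):
            act = "identity" if i == len(widths) - 2 else "tanh"
            self.layers.append(DenseLayer(a, b, act, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i}.{k}": v
            for i, layer in enumerate(self.layers)
            for k, v in layer.params().items()
        }

    def grads(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i}.{k}": v
            for i, layer in enumerate(self.layers)
            for k, v in layer.grads.items()
        }

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for key in layer.params():
                getattr(layer, key)[...] = values[f"layer{i}.{key}"]


class AdamW:
    """AdamW over a named parameter dict; state is serializable for resume."""

    def __init__(self, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        b1, b2 = self.betas
        self.t += 1
        for key in params:
            g = grads.get(key)
            if g is None:
                continue
            p = params[key]
            if key not in self.m:
                self.m[key] = np.zeros_like(p)
                self.v[key] = np.zeros_like(p)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g**2
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            # decoupled weight decay, skipped for biases and 1-d scale params
            if self.weight_decay and p.ndim > 1:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def state(self) -> dict:
        return {"m": dict(self.m), "v": dict(self.v), "t": self.t}

    def load_state(self, state: dict) -> None:
        self.m = {k: np.array(v) for k, v in state["m"].items()}
        self.v = {k: np.array(v) for k, v in state["v"].items()}
        self.t = int(state["t"])
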