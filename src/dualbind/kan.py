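"""Kolmogorov-Arnold network layers with sinusoidal learnable edge functions.

Each edge (input j -> output k) carries a truncated Fourier series with
learnable amplitudes and phases over a fixed set of base frequencies, plus an
optional linear term:

    y_k = b_k + sum_j W[k,j] x_j
              + sum_j sum_h A[k,j,h] * sin(omega_h * x_j + phi[k,j,h])

All parameters (A, phi, W, b) are trainable; the base frequencies omega_h are
fixed.  Internally the sinusoid is expanded as
``A cos(phi) sin(wx) + A sin(phi) cos(wx)`` so the (N, in, H) sin/cos tensors
are shared across output units; gradients are mapped back to amplitude/phase.

Layers support an optional per-position input mask that removes the *entire*
edge contribution of masked inputs (both the linear and the sinusoidal term).
Zeroing the input alone would not suffice once phases are trained, because
``A sin(phi)`` is generally nonzero at x = 0; masking the contribution keeps
padded inputs exactly inert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Raised for invalid layer/stack specifications."""


@dataclass(frozen=True)
class KanLayerSpec:
    """Shape and parameterization of one KAN layer."""

    in_width: int
    out_width: int
    num_harmonics: int = 2
    include_linear_residual: bool = True
    base_freqs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.in_width < 1 or self.out_width < 1:
            raise ConfigurationError("layer widths must be >= 1")
        if self.num_harmonics < 1:
            raise ConfigurationError("num_harmonics must be >= 1")
        if self.base_freqs is not None and len(self.base_freqs) != self.num_harmonics:
            raise ConfigurationError("base_freqs length must equal num_harmonics")

    @property
    def frequencies(self) -> np.ndarray:
        if self.base_freqs is not None:
            return np.asarray(self.base_freqs, dtype=np.float64)
        return np.arange(1, self.num_harmonics + 1, dtype=np.float64)


def _semi_orthogonal(rng: np.random.Generator, out_width: int, in_width: int) -> np.ndarray:
    a = rng.standard_normal((max(out_width, in_width), min(out_width, in_width)))
    q, _ = np.linalg.qr(a)
    q = q[: max(out_width, in_width), : min(out_width, in_width)]
    return np.ascontiguousarray(q if out_width >= in_width else q.T)


class KanLayer:
    """A trainable KAN layer (see module docstring for the edge function)."""

    def __init__(self, spec: KanLayerSpec, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        rng = rng if rng is not None else np.random.default_rng(0)
        n_in, n_out, nh = spec.in_width, spec.out_width, spec.num_harmonics
        scale = 1.0 / np.sqrt(n_in * nh)
        self.amp = (rng.standard_normal((n_out, n_in, nh)) * scale).astype(self.dtype)
        self.phase = np.zeros((n_out, n_in, nh), dtype=self.dtype)
        if spec.include_linear_residual:
            self.weight = _semi_orthogonal(rng, n_out, n_in).astype(self.dtype)
        else:
            self.weight = None
        self.bias = np.zeros(n_out, dtype=self.dtype)
        self.grads: dict[str, np.ndarray] = {}
        self._cache: tuple | None = None

    # -- parameter registry -------------------------------------------------

    def params(self) -> dict[str, np.ndarray]:
        out = {"amp": self.amp, "phase": self.phase, "bias": self.bias}
        if self.weight is not None:
            out["weight"] = self.weight
        return out

    def zero_grads(self) -> None:
        self.grads = {}

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, input_mask: np.ndarray | None = None) -> np.ndarray:
        """Apply the layer to a batch ``x`` of shape (N, in_width).

        ``input_mask`` (N, in_width), if given, multiplies the full edge
        contribution of each input; masked (0) inputs are inert.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 2 or x.shape[1] != self.spec.in_width:
            raise ValueError(
                f"input shape {x.shape} incompatible with in_width {self.spec.in_width}"
            )
        freqs = self.spec.frequencies.astype(self.dtype)
        ang = x[:, :, None] * freqs[None, None, :]
        s, c = np.sin(ang), np.cos(ang)
        if input_mask is not None:
            m = np.asarray(input_mask, dtype=self.dtype)
            if m.shape != x.shape:
                raise ValueError(f"mask shape {m.shape} != input shape {x.shape}")
            s = s * m[:, :, None]
            c = c * m[:, :, None]
            x_eff = x * m
        else:
            x_eff = x
        p = self.amp * np.cos(self.phase)
        q = self.amp * np.sin(self.phase)
        n, n_in = x.shape
        nh = n_in * len(freqs)
        # contract (n, in*H) x (out, in*H)^T through BLAS
        y = s.reshape(n, nh) @ p.reshape(-1, nh).T + c.reshape(n, nh) @ q.reshape(-1, nh).T
        if self.weight is not None:
            y += x_eff @ self.weight.T
        y += self.bias
        self._cache = (x_eff, s, c, input_mask)
        return y

    def backward(self, grad_out: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        """Backpropagate ``grad_out`` (N, out_width); accumulates parameter
        gradients in ``self.grads`` and returns the gradient w.r.t. the input
        (or ``None`` when ``need_input_grad`` is False, e.g. for a first layer
        fed by fixed inputs)."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        x_eff, s, c, input_mask = self._cache
        freqs = self.spec.frequencies.astype(self.dtype)
        g = np.asarray(grad_out, dtype=self.dtype)
        cphi, sphi = np.cos(self.phase), np.sin(self.phase)
        n = g.shape[0]
        n_in, nh = self.spec.in_width, self.spec.in_width * len(freqs)
        shape3 = self.amp.shape
        dp = (g.T @ s.reshape(n, nh)).reshape(shape3)
        dq = (g.T @ c.reshape(n, nh)).reshape(shape3)
        d_amp = dp * cphi + dq * sphi
        d_phase = self.amp * (dq * cphi - dp * sphi)
        self.grads["amp"] = self.grads.get("amp", 0) + d_amp
        self.grads["phase"] = self.grads.get("phase", 0) + d_phase
        self.grads["bias"] = self.grads.get("bias", 0) + g.sum(axis=0)
        if self.weight is not None:
            self.grads["weight"] = self.grads.get("weight", 0) + g.T @ x_eff
        if not need_input_grad:
            return None
        p = self.amp * cphi
        q = self.amp * sphi
        gp = (g @ p.reshape(-1, nh)).reshape(n, n_in, -1)
        gq = (g @ q.reshape(-1, nh)).reshape(n, n_in, -1)
        dx = ((gp * c - gq * s) * freqs[None, None, :]).sum(axis=2)
        if self.weight is not None:
            dx += g @ self.weight
        if input_mask is not None:
            dx = dx * np.asarray(input_mask, dtype=self.dtype)
        return dx


def kan_forward(x: np.ndarray, layer: KanLayer) -> np.ndarray:
    """Apply one layer to a single vector of length ``in_width``."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("kan_forward expects a 1-D input vector")
    return layer.forward(x[None, :])[0]


class KanStack:
    """A sequential composition of KAN layers; an empty stack is the identity."""

    def __init__(self, layers: Sequence[KanLayer]):
        self.layers = list(layers)
        for a, b in zip(self.layers, self.layers[1:]):
            if a.spec.out_width != b.spec.in_width:
                raise ConfigurationError(
                    f"incompatible stack widths: {a.spec.out_width} -> {b.spec.in_width}"
                )

    @classmethod
    def from_widths(
        cls,
        widths: Sequence[int],
        num_harmonics: int = 2,
        rng: np.random.Generator | None = None,
        include_linear_residual: bool = True,
        dtype=np.float64,
    ) -> "KanStack":
        rng = rng if rng is not None else np.random.default_rng(0)
        layers = [
            KanLayer(
                KanLayerSpec(
                    in_width=i, out_width=o, num_harmonics=num_harmonics,
                    include_linear_residual=include_linear_residual,
                ),
                rng,
                dtype=dtype,
            )
            for i, o in zip(widths, widths[1:])
        ]
        return cls(layers)

    @property
    def in_width(self) -> int | None:
        return self.layers[0].spec.in_width if self.layers else None

    @property
    def out_width(self) -> int | None:
        return self.layers[-1].spec.out_width if self.layers else None

    def forward(self, x: np.ndarray, input_mask: np.ndarray | None = None) -> np.ndarray:
        """Apply the stack to (N, in_width); the mask applies to the first layer only."""
        h = np.asarray(x)
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, input_mask=input_mask if i == 0 else None)
        return h

    def backward(self, grad_out: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        g = grad_out
        for i, layer in zip(range(len(self.layers) - 1, -1, -1), reversed(self.layers)):
            g = layer.backward(g, need_input_grad=need_input_grad or i > 0)
        return g

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.params().items():
                out[f"layer{i}.{key}"] = val
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.grads.items():
                out[f"layer{i}.{key}"] = val
        return out

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for key in layer.params():
                arr = values[f"layer{i}.{key}"]
                getattr(layer, key)[...] = arr


def stack_forward(x: np.ndarray, layers: Sequence[KanLayer]) -> np.ndarray:
    """Apply a sequence of layers to a single vector; empty sequence = identity."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("stack_forward expects a 1-D input vector")
    return KanStack(layers).forward(x[None, :])[0]
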