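"""Layers and the Adam optimizer, built on the autograd Tensor.

Convolutions are expressed as sums of zero-shifted matmuls ('same' padding),
which keeps the backward pass simple and exact.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Adam",
    "glorot",
    "conv1d",
    "conv2d",
    "maxpool1d",
    "maxpool2d",
    "layer_norm",
]


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: tracks named parameters; supports state save/restore."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}

    def param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self._params[k].data = np.asarray(v, dtype=np.float64).copy()

    def set_zero_weights(self) -> None:
        """All-zero parameters (useful for degenerate-output checks)."""
        for p in self.parameters():
            p.data = np.zeros_like(p.data)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def conv1d(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """'same' 1-D convolution along axis 1.

    ``x``: (B, L, C_in); ``W``: (k, C_in, C_out); ``b``: (C_out,).
    """
    k = W.shape[0]
    pad = k // 2
    out = None
    for j in range(k):
        term = x.shift(j - pad, axis=1) @ W[j]
        out = term if out is None else out + term
    return out + b


def conv2d(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """'same' 2-D convolution over axes (1, 2).

    ``x``: (B, H, W, C_in); ``W``: (kh, kw, C_in, C_out); ``b``: (C_out,).
    """
    kh, kw = W.shape[0], W.shape[1]
    ph, pw = kh // 2, kw // 2
    out = None
    for dy in range(kh):
        for dx in range(kw):
            shifted = x.shift(dy - ph, axis=1).shift(dx - pw, axis=2)
            term = shifted @ W[dy, dx]
            out = term if out is None else out + term
    return out + b


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling along axis 1 (trailing remainder dropped)."""
    B, L, C = x.shape
    Lp = (L // size) * size
    x = x[:, :Lp, :]
    return x.reshape(B, Lp // size, size, C).max(axis=2)


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping 2-D max pooling over axes (1, 2)."""
    B, H, W, C = x.shape
    Hp, Wp = (H // size) * size, (W // size) * size
    x = x[:, :Hp, :Wp, :]
    x = x.reshape(B, Hp // size, size, Wp, C).max(axis=2)
    return x.reshape(B, Hp // size, Wp // size, size, C).max(axis=3)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    normed = centered * (var + eps) ** -0.5
    return normed * gamma + beta
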