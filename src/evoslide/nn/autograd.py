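"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the classifier heads need: broadcasting
arithmetic, batched matmul, elementwise nonlinearities, reductions, axis
max (pooling), zero-filled shifts (convolutions are sums of shifted
matmuls), basic indexing, concatenation, softmax, and a fused
softmax-cross-entropy loss.  Everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = lambda: None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing ----------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            t._backward()

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out._backward = _backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _backward():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * p * self.data ** (p - 1))

        out._backward = _backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data),
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def _backward():
            g = out.grad
            if self.requires_grad:
                gA = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(gA, self.data.shape))
            if other.requires_grad:
                gB = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gB, other.data.shape))

        out._backward = _backward
        return out

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * (self.data > 0))

        out._backward = _backward
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * (1.0 - y * y))

        out._backward = _backward
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * y * (1.0 - y))

        out._backward = _backward
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad * y)

        out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        out._backward = _backward
        return out

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int) -> "Tensor":
        y = self.data.max(axis=axis)
        out = Tensor(y, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                expanded = np.expand_dims(y, axis)
                mask = self.data == expanded
                # split gradient equally among ties for symmetry
                counts = mask.sum(axis=axis, keepdims=True)
                g = np.expand_dims(out.grad, axis) * mask / counts
                self._accumulate(g)

        out._backward = _backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = _backward
        return out

    def transpose(self, axes) -> "Tensor":
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inverse = np.argsort(axes)

        def _backward():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inverse))

        out._backward = _backward
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accumulate(g)

        out._backward = _backward
        return out

    def shift(self, offset: int, axis: int) -> "Tensor":
        """Zero-filled shift: ``y[t] = x[t + offset]`` along ``axis``."""
        out_data = np.zeros_like(self.data)
        n = self.data.shape[axis]
        src = [slice(None)] * self.data.ndim
        dst = [slice(None)] * self.data.ndim
        if offset >= 0:
            src[axis] = slice(offset, n)
            dst[axis] = slice(0, n - offset)
        else:
            src[axis] = slice(0, n + offset)
            dst[axis] = slice(-offset, n)
        out_data[tuple(dst)] = self.data[tuple(src)]
        out = Tensor(out_data, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[tuple(src)] = out.grad[tuple(dst)]
                self._accumulate(g)

        out._backward = _backward
        return out


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.data.ndim
                idx[axis] = slice(start, stop)
                t._accumulate(out.grad[tuple(idx)])

    out._backward = _backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def _backward():
        if x.requires_grad:
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    out._backward = _backward
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of softmax(logits) against one-hot rows."""
    z = logits.data
    m = z.max(axis=-1, keepdims=True)
    logsumexp = m + np.log(np.exp(z - m).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    n = z.shape[0]
    loss_val = -(onehot * logp).sum() / n
    out = Tensor(loss_val, logits.requires_grad, (logits,))

    def _backward():
        if logits.requires_grad:
            p = np.exp(logp)
            logits._accumulate(out.grad * (p - onehot) / n)

    out._backward = _backward
    return out
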