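"""Minimal reverse-mode autodiff on numpy arrays.

Only the operations needed by the models in this package are provided.
All data is kept in float32; gradients are accumulated into ``.grad``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self._grad_owned = False

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        # First contribution is stored by reference (possibly aliasing an
        # upstream array); a second contribution forces a private copy
        # before in-place accumulation.
        if self.grad is None:
            self.grad = grad if grad.dtype == np.float32 \
                else grad.astype(np.float32)
            self._grad_owned = False
        else:
            if not self._grad_owned:
                self.grad = self.grad + grad
                self._grad_owned = True
            else:
                self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- construction helper ----------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad or p._parents for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, parents=parents, backward=backward)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), bw)

    def __matmul__(self, other):
        # 2-D or batched matmul only; 1-D operands are not supported.
        other = self._coerce(other)
        out_data = self.data @ other.data

        def bw(g):
            a, b = self.data, other.data
            ga = g @ b.swapaxes(-1, -2)
            gb = a.swapaxes(-1, -2) @ g
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), bw)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            self._accumulate(g / self.data)

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def erf(self):
        out_data = _erf(self.data).astype(np.float32)

        def bw(g):
            self._accumulate(g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data ** 2))

        return self._make(out_data, (self,), bw)

    def abs(self):
        out_data = np.abs(self.data)

        def bw(g):
            self._accumulate(g * np.sign(self.data))

        return self._make(out_data, (self,), bw)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)

        def bw(g):
            self._accumulate(g * ((self.data > lo) & (self.data < hi)))

        return self._make(out_data, (self,), bw)

    def relu(self):
        out_data = np.maximum(self.data, 0)

        def bw(g):
            self._accumulate(g * (self.data > 0))

        return self._make(out_data, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        out_data = np.where(self.data > 0, self.data,
                            np.float32(slope) * self.data)

        def bw(g):
            self._accumulate(
                g * np.where(self.data > 0, np.float32(1.0), np.float32(slope)))

        return self._make(out_data, (self,), bw)

    def elu(self, alpha: float = 1.0):
        d = self.data
        out_data = np.where(d > 0, d, np.float32(alpha) * np.expm1(d))

        def bw(g):
            self._accumulate(
                g * np.where(d > 0, np.float32(1.0), out_data + np.float32(alpha)))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        # stable logistic via tanh
        out_data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data.astype(np.float32), (self,), bw)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                shape = [1 if i in axes else s for i, s in enumerate(self.data.shape)]
                g = g.reshape(shape)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accumulate(g.reshape(self.data.shape))

        return self._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return self._make(out_data, (self,), bw)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"
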