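"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based autograd engine providing exactly the operations the
segmentation models need: broadcasting arithmetic, the pointwise
nonlinearities (ReLU, sigmoid, tanh, log, power), reductions, channel
concatenation and stride-1 "same" 2D convolution.  Arrays are float64
throughout; gradients are checked against central finite differences in
the test suite.

Only scalar outputs may seed ``backward()`` — every training loss here is
a scalar mean, so nothing more general is needed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "astensor",
    "concat",
    "conv2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autograd graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- construction helpers -----------------------------------------
    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = astensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = astensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        other = astensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), bw)

    # -- nonlinearities ------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return Tensor._make(t, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through strictly inside the bounds."""
        inside = (self.data > lo) & (self.data < hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)

    # -- reductions and reshaping --------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 2D convolution with "same" zero padding.

    ``x``: (B, C, H, W); ``weight``: (O, C, k, k) with k odd;
    ``bias``: (O,) or None.  Output: (B, O, H, W).
    """
    x = astensor(x)
    B, C, H, W = x.data.shape
    O, Cw, k, k2 = weight.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Cw}")
    if k != k2 or k % 2 == 0:
        raise ValueError("kernels must be square with odd size")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    # (B, C, H, W, k, k) view over the padded input
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * H * W, C * k * k
    )
    wmat = weight.data.reshape(O, C * k * k)
    y = col @ wmat.T
    out_data = y.reshape(B, H, W, O).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * H * W, O)
        if weight.requires_grad:
            weight._accum((gm.T @ col).reshape(O, C, k, k))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = (gm @ wmat).reshape(B, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + H, j : j + W] += dcol[:, :, :, :, i, j]
            x._accum(dxp[:, :, p : p + H, p : p + W])

    return Tensor._make(out_data, parents, bw)
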