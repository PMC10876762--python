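"""Reverse-mode automatic differentiation on NumPy arrays.

The pulse-design loop needs gradients of a scalar cost with respect to every
RF and gradient waveform sample, propagated through the forward models (the
small-tip-angle system matrix or a full hard-pulse Bloch simulation), the SAR
quadratic forms and the penalty terms.  This module provides the minimal
tape-based engine used for that: a :class:`Tensor` wrapping a float64
``ndarray``, a set of differentiable primitives, and dispatch helpers so the
same kernel code runs on plain arrays (fast evaluation) or Tensors
(optimization).

Only real arithmetic is implemented; complex quantities (RF samples,
sensitivities, transverse magnetization) are carried as explicit
real/imaginary pairs by the callers.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "exp",
    "sin",
    "cos",
    "sqrt",
    "atan2",
    "relu",
    "asum",
    "amean",
    "amax",
    "cumsum",
    "concatenate",
    "reshape",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # collapse broadcast (size-1) axes
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A float64 array node on the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_bwd")

    # make numpy defer to our reflected operators instead of coercing
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, _parents=(), _bwd=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = _parents
        self._bwd = _bwd

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # ------------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Backpropagate from this scalar node, filling ``.grad`` on leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        # iterative post-order topological sort
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return _add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _add(self, _neg_or_np(other))

    def __rsub__(self, other):
        return _add(_neg(self), other)

    def __neg__(self):
        return _neg(self)

    def __truediv__(self, other):
        return _div(self, other)

    def __rtruediv__(self, other):
        return _div(other, self)

    def __pow__(self, p):
        return _pow(self, p)

    def __matmul__(self, other):
        return _matmul(self, other)

    def __rmatmul__(self, other):
        return _matmul(other, self)

    def __getitem__(self, idx):
        return _getitem(self, idx)


def tensor(data) -> Tensor:
    """Create a leaf Tensor."""
    return Tensor(data)


def _val(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _neg_or_np(x):
    return _neg(x) if isinstance(x, Tensor) else -np.asarray(x, dtype=np.float64)


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------

def _add(a, b):
    av, bv = _val(a), _val(b)
    parents = tuple(t for t in (a, b) if isinstance(t, Tensor))

    def bwd(g):
        if isinstance(a, Tensor):
            a._accumulate(g)
        if isinstance(b, Tensor):
            b._accumulate(g)

    return Tensor(av + bv, parents, bwd)


def _mul(a, b):
    av, bv = _val(a), _val(b)
    parents = tuple(t for t in (a, b) if isinstance(t, Tensor))

    def bwd(g):
        if isinstance(a, Tensor):
            a._accumulate(g * bv)
        if isinstance(b, Tensor):
            b._accumulate(g * av)

    return Tensor(av * bv, parents, bwd)


def _neg(a):
    def bwd(g):
        a._accumulate(-g)

    return Tensor(-a.data, (a,), bwd)


def _div(a, b):
    av, bv = _val(a), _val(b)
    parents = tuple(t for t in (a, b) if isinstance(t, Tensor))

    def bwd(g):
        if isinstance(a, Tensor):
            a._accumulate(g / bv)
        if isinstance(b, Tensor):
            b._accumulate(-g * av / (bv * bv))

    return Tensor(av / bv, parents, bwd)


def _pow(a, p):
    if isinstance(p, Tensor):
        raise TypeError("only constant exponents are supported")
    p = float(p)

    def bwd(g):
        a._accumulate(g * p * np.power(a.data, p - 1.0))

    return Tensor(np.power(a.data, p), (a,), bwd)


def _matmul(a, b):
    av, bv = _val(a), _val(b)
    if av.ndim != 2 or bv.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    parents = tuple(t for t in (a, b) if isinstance(t, Tensor))

    def bwd(g):
        if isinstance(a, Tensor):
            a._accumulate(g @ bv.T)
        if isinstance(b, Tensor):
            b._accumulate(av.T @ g)

    return Tensor(av @ bv, parents, bwd)


def _getitem(a, idx):
    def bwd(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        a._accumulate(buf)

    return Tensor(a.data[idx], (a,), bwd)


# ----------------------------------------------------------------------
# elementwise functions (dispatch on type)
# ----------------------------------------------------------------------

def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(x)
    out = np.exp(x.data)

    def bwd(g):
        x._accumulate(g * out)

    return Tensor(out, (x,), bwd)


def sin(x):
    if not isinstance(x, Tensor):
        return np.sin(x)

    def bwd(g):
        x._accumulate(g * np.cos(x.data))

    return Tensor(np.sin(x.data), (x,), bwd)


def cos(x):
    if not isinstance(x, Tensor):
        return np.cos(x)

    def bwd(g):
        x._accumulate(-g * np.sin(x.data))

    return Tensor(np.cos(x.data), (x,), bwd)


def sqrt(x):
    if not isinstance(x, Tensor):
        return np.sqrt(x)
    out = np.sqrt(x.data)

    def bwd(g):
        x._accumulate(g / (2.0 * out))

    return Tensor(out, (x,), bwd)


def atan2(y, x):
    if not isinstance(y, Tensor) and not isinstance(x, Tensor):
        return np.arctan2(y, x)
    yv, xv = _val(y), _val(x)
    denom = xv * xv + yv * yv
    parents = tuple(t for t in (y, x) if isinstance(t, Tensor))

    def bwd(g):
        if isinstance(y, Tensor):
            y._accumulate(g * xv / denom)
        if isinstance(x, Tensor):
            x._accumulate(-g * yv / denom)

    return Tensor(np.arctan2(yv, xv), parents, bwd)


def relu(x):
    """max(x, 0) elementwise; subgradient 0 at the kink."""
    if not isinstance(x, Tensor):
        return np.maximum(x, 0.0)
    mask = x.data > 0.0

    def bwd(g):
        x._accumulate(g * mask)

    return Tensor(np.where(mask, x.data, 0.0), (x,), bwd)


# ----------------------------------------------------------------------
# reductions and shape ops
# ----------------------------------------------------------------------

def asum(x, axis=None):
    if not isinstance(x, Tensor):
        return np.sum(x, axis=axis)
    out = np.sum(x.data, axis=axis)

    def bwd(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.data.shape))
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            g_exp = np.expand_dims(g, axes)
            x._accumulate(np.broadcast_to(g_exp, x.data.shape))

    return Tensor(out, (x,), bwd)


def amean(x, axis=None):
    if not isinstance(x, Tensor):
        return np.mean(x, axis=axis)
    if axis is None:
        n = x.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([x.data.shape[i] for i in axes]))
    return asum(x, axis=axis) * (1.0 / n)


def amax(x):
    """Global maximum; gradient split equally among the attaining entries."""
    if not isinstance(x, Tensor):
        return np.max(x)
    out = np.max(x.data)
    mask = x.data == out

    def bwd(g):
        x._accumulate(g * mask / mask.sum())

    return Tensor(out, (x,), bwd)


def cumsum(x, axis):
    if not isinstance(x, Tensor):
        return np.cumsum(x, axis=axis)

    def bwd(g):
        rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
        x._accumulate(rev)

    return Tensor(np.cumsum(x.data, axis=axis), (x,), bwd)


def concatenate(parts: Sequence, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    vals = [_val(p) for p in parts]
    sizes = [v.shape[axis] for v in vals]
    offsets = np.cumsum([0] + sizes)
    parents = tuple(p for p in parts if isinstance(p, Tensor))

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if isinstance(p, Tensor):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate(vals, axis=axis), parents, bwd)


def reshape(x, shape):
    if not isinstance(x, Tensor):
        return np.reshape(x, shape)

    def bwd(g):
        x._accumulate(g.reshape(x.data.shape))

    return Tensor(x.data.reshape(shape), (x,), bwd)
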