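"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the style of the classic define-by-run
frameworks.  Every operation records its parents and a backward closure;
crucially the backward closures are themselves written in terms of engine
operations, so calling :meth:`Tensor.backward` with ``create_graph=True``
yields gradients that are again differentiable.  That second-order path is
what the Wasserstein-GAN gradient penalty needs (the penalty is a function
of the critic's input gradient, and its parameter gradient requires
differentiating through the first backward pass).

Design constraints:

- float32 by default (images and network activations are small, 64x64).
- Broadcasting follows NumPy; backward un-broadcasts by summation.
- Piecewise-linear ops (relu family, max, abs at 0) use the standard
  sub-gradient convention; their masks are treated as constants, which is
  the measure-zero-correct choice for double backprop.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "as_tensor", "concat", "stack"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _grad_on() -> bool:
    return _GRAD_ENABLED[-1]


def as_tensor(x, dtype=np.float32) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward_fn: Callable | None = None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: "Tensor | None" = None
        self._parents = tuple(parents)
        self._backward_fn = backward_fn

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

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction --------------------------------------------
    @staticmethod
    def _make(data, parents, backward_fn):
        req = _grad_on() and any(p.requires_grad for p in parents)
        if req:
            return Tensor(data, requires_grad=True, parents=parents,
                          backward_fn=backward_fn)
        return Tensor(data)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.data.dtype)
        out_data = self.data + other.data
        def bw(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.data.dtype)
        out_data = self.data * other.data
        def bw(g):
            return (_unbroadcast(g * other, self.shape),
                    _unbroadcast(g * self, other.shape))
        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.data.dtype)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other, self.data.dtype) * self.pow(-1.0)

    def pow(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e
        def bw(g):
            return (g * (self.pow(e - 1.0) * e),)
        return Tensor._make(out_data, (self,), bw)

    __pow__ = pow

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        out_data = np.exp(self.data)
        def bw(g, out_ref=None):
            return (g * self.exp(),)
        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)
        def bw(g):
            return (g * self.pow(-1.0),)
        return Tensor._make(out_data, (self,), bw)

    def abs(self):
        out_data = np.abs(self.data)
        def bw(g):
            return (g * Tensor(np.sign(self.data).astype(self.data.dtype)),)
        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)
        def bw(g):
            s = self.sigmoid()
            return (g * s * (1.0 - s),)
        return Tensor._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)
        def bw(g):
            t = self.tanh()
            return (g * (1.0 - t * t),)
        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        return self.leaky_relu(0.0)

    def leaky_relu(self, negative_slope: float = 0.2):
        out_data = np.where(self.data > 0, self.data,
                            self.data * negative_slope)
        def bw(g):
            mask = Tensor(np.where(self.data > 0, 1.0,
                                   negative_slope).astype(self.data.dtype))
            return (g * mask,)
        return Tensor._make(out_data, (self,), bw)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)
        def bw(g):
            return (g.reshape(old),)
        return Tensor._make(out_data, (self,), bw)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)
        def bw(g):
            return (g.transpose(inv),)
        return Tensor._make(out_data, (self,), bw)

    def pad2d(self, pad: int):
        """Zero-pad the last two axes symmetrically by ``pad``."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, width)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        def bw(g):
            return (g.slice_(sl),)
        return Tensor._make(out_data, (self,), bw)

    def slice_(self, key):
        out_data = self.data[key]
        shape = self.shape
        def bw(g):
            buf = Tensor(np.zeros(shape, dtype=g.data.dtype))
            return (buf.index_add(key, g),)
        return Tensor._make(out_data, (self,), bw)

    def index_add(self, key, value: "Tensor"):
        """Out-of-place scatter-add of ``value`` into a copy of self at ``key``."""
        out_data = self.data.copy()
        if isinstance(key, np.ndarray):
            np.add.at(out_data, key, value.data)
        else:
            out_data[key] = out_data[key] + value.data
        def bw(g):
            return (g, g.slice_(key))
        return Tensor._make(out_data, (self, value), bw)

    def take(self, indices: np.ndarray):
        """Gather from the flattened tensor; backward is scatter-add."""
        flat = self.reshape(self.size)
        out_data = flat.data[indices]
        n = self.size
        def bw(g):
            buf = Tensor(np.zeros(n, dtype=g.data.dtype))
            return (buf.index_add(indices, g),)
        out = Tensor._make(out_data, (flat,), bw)
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape
        def bw(g):
            if axis is None:
                return (g.reshape((1,) * len(shape)).broadcast_to(shape),)
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(a % len(shape) for a in axes)
            if not keepdims:
                kshape = tuple(1 if i in axes else s
                               for i, s in enumerate(shape))
                g = g.reshape(kshape)
            return (g.broadcast_to(shape),)
        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def broadcast_to(self, shape):
        shape = tuple(shape)
        out_data = np.broadcast_to(self.data, shape)  # strided view, no copy
        old = self.shape
        def bw(g):
            return (_unbroadcast(g, old),)
        return Tensor._make(out_data, (self,), bw)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient splits evenly over argmax ties."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        shape = self.shape
        def bw(g):
            expanded = self.data.max(axis=axis, keepdims=True)
            hit = self.data == expanded
            denom = hit.sum(axis=axis, keepdims=True)
            mask = Tensor((hit / denom).astype(self.data.dtype))
            if not keepdims:
                kshape = tuple(1 if i == axis % len(shape) else s
                               for i, s in enumerate(shape))
                g = g.reshape(kshape)
            return ((g.broadcast_to(shape)) * mask,)
        return Tensor._make(out_data, (self,), bw)

    # -- linear algebra -------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = as_tensor(other, self.data.dtype)
        out_data = self.data @ other.data
        def bw(g):
            a, b = self, other
            if a.ndim == 2 and b.ndim == 3 and g.ndim == 3:
                # batched (co,k)@(n,k,l): fold batch into one GEMM for da
                n, k, l = b.shape
                co = a.shape[0]
                ga = (g.transpose((1, 0, 2)).reshape(co, n * l)
                      .matmul(b.transpose((0, 2, 1)).reshape(n * l, k)))
                gb = a.swap_last().matmul(g)
                return (ga, gb)
            ga = g.matmul(b.swap_last())
            gb = a.swap_last().matmul(g)
            return (_unbroadcast_matmul(ga, a.shape),
                    _unbroadcast_matmul(gb, b.shape))
        return Tensor._make(out_data, (self, other), bw)

    __matmul__ = matmul

    def swap_last(self):
        axes = list(range(self.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return self.transpose(axes)

    # -- backward -------------------------------------------------------
    def backward(self, grad: "Tensor | None" = None,
                 create_graph: bool = False):
        """Backpropagate; populates ``.grad`` on every reachable tensor
        that ``requires_grad``.  With ``create_graph=True`` the gradients
        are themselves recorded for further differentiation."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = Tensor(np.ones_like(self.data))

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, Tensor] = {id(self): grad}
        ctx = contextlib.nullcontext() if create_graph else no_grad()
        with ctx:
            for node in reversed(topo):
                g = grads.pop(id(node), None)
                if g is None:
                    continue
                if node._backward_fn is None:
                    # leaf: accumulate .grad (interior grads are transient)
                    node.grad = g if node.grad is None else node.grad + g
                    continue
                parent_grads = node._backward_fn(g)
                for p, pg in zip(node._parents, parent_grads):
                    if pg is None or not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _unbroadcast_matmul(g: Tensor, shape) -> Tensor:
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i in range(len(shape) - 2)
                 if shape[i] == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        outs = []
        for t, o, s in zip(tensors, offsets, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(o), int(o + s))
            outs.append(g.slice_(tuple(sl)))
        return tuple(outs)
    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis % (t.ndim + 1), 1)
        expanded.append(t.reshape(shape))
    return concat(expanded, axis=axis)
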