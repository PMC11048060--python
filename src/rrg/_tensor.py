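"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records, for every operation,
a closure that propagates the output gradient to the operation's inputs.
``backward()`` runs the closures in reverse topological order.  The op set is
exactly what a small transformer encoder–decoder needs: broadcasting
arithmetic, matmul (incl. batched 4-D), exp/log/tanh, reductions, reshaping,
concatenation, integer-array gather (embeddings) and a numerically stable
``log_softmax``.  Everything runs in float64.

``no_grad()`` disables graph construction, which makes pure-inference decoding
loops considerably cheaper.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager: operations inside build no backward graph."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        if _GRAD_ENABLED and (backward is not None):
            self._parents = parents
            self._backward = backward
        else:
            self._parents = ()
            self._backward = None

    # ------------------------------------------------------------------ misc
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self._backward is not None})"

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (decoding loops)
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
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)

        return Tensor(-self.data, True, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g, a=self, p=p):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor(out_data, True, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g, a=self, b=other):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, o=out_data):
            a._accum(g * o)

        return Tensor(out_data, True, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            a._accum(g / a.data)

        return Tensor(np.log(self.data), True, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g, a=self, o=out_data):
            a._accum(g * (1.0 - o * o))

        return Tensor(out_data, True, (self,), bwd)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor(out_data, True, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------------- shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bwd(g, a=self):
            a._accum(g.reshape(a.data.shape))

        return Tensor(out_data, True, (self,), bwd)

    def swapaxes(self, ax1: int, ax2: int):
        out_data = np.swapaxes(self.data, ax1, ax2)

        def bwd(g, a=self, ax1=ax1, ax2=ax2):
            a._accum(np.swapaxes(g, ax1, ax2))

        return Tensor(out_data, True, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor(out_data, True, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g, ts=tensors, sizes=sizes, axis=axis):
        offset = 0
        for t, s in zip(ts, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offset, offset + s)
            t._accum(g[tuple(sl)])
            offset += s

    return Tensor(out_data, True, tuple(tensors), bwd)


def gather_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup: rows of `table` (V, D) at integer array `ids`."""
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def bwd(g, t=table, ids=ids):
        full = np.zeros_like(t.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, t.data.shape[-1]))
        t._accum(full)

    return Tensor(out_data, True, (table,), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax; the max shift is treated as constant."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(shift)
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def gelu(x: Tensor) -> Tensor:
    """GELU, tanh approximation (composite of differentiable primitives)."""
    c = float(np.sqrt(2.0 / np.pi))
    inner = (x + x * x * x * 0.044715) * c
    return x * (inner.tanh() + 1.0) * 0.5
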