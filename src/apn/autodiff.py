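"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine supports exactly the operations the graph encoders, the
attention gates and the prototype head need: elementwise arithmetic with
broadcasting, 2-D matrix products, row gathering / segment reduction for
message passing, the usual nonlinearities, and reductions.  Gradients are
accumulated by topological-order backpropagation from a scalar loss.

Every op is validated against central finite differences in the test
suite; keep new ops covered the same way.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking ``ndarray * Tensor``

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: molecule batches can make deep graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    # -- nonlinearities -------------------------------------------------------
    def sigmoid(self):
        # output kept strictly inside (0, 1): saturated gates stay gates
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        s = np.clip(s, 1e-12, 1.0 - 1e-12)

        def bwd(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, alpha: float = 0.2):
        mask = self.data > 0
        slope = np.where(mask, 1.0, alpha)

        def bwd(g):
            self._accum(g * slope)

        return self._make(self.data * slope, (self,), bwd)

    def exp(self):
        e = np.exp(np.clip(self.data, -500, 500))

        def bwd(g):
            self._accum(g * e)

        return self._make(e, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        r = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / r)

        return self._make(r, (self,), bwd)

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only where unclipped."""
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g):
            self._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), bwd)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]``; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=np.int64)

    def bwd(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accum(acc)

    return x._make(x.data[idx], (x,), bwd)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out, segment_ids, x.data)

    def bwd(g):
        x._accum(g[segment_ids])

    return x._make(out, (x,), bwd)


def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bwd
    return out
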