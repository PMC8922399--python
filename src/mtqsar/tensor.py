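"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the package's lightweight tensor engine: a small set of
differentiable array operations (dense linear algebra, elementwise
nonlinearities, row gather and segment reduction) sufficient to express
and train an attentive message-passing network on batched molecular
graphs.  Gradients are accumulated by reverse topological traversal of
the recorded operation graph.

All arithmetic is float64 and single-threaded, so results are bitwise
reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "segment_softmax",
    "segment_mean",
    "leaky_relu",
    "sigmoid",
    "tanh",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an attached gradient and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # -- construction -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias a child's grad buffer
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def _accumulate_owned(self, g: np.ndarray) -> None:
        """Accumulate a freshly allocated buffer the caller will not reuse."""
        if self.grad is None:
            self.grad = g
        else:
            self.grad += g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _node(self.data / other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _node(self.data @ other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise ---------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = _node(val, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bwd
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out

    # -- autodiff driver ----------------------------------------------
    def backward(self):
        """Reverse accumulation from this (scalar or any-shape) node."""
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad for p in out._parents)
    return out


# -- nonlinearities ----------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    pos = x.data > 0
    out = _node(np.where(pos, x.data, slope * x.data), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * np.where(pos, 1.0, slope))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = _node(val, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * val * (1.0 - val))

    out._backward = bwd
    return out


def tanh(x: Tensor) -> Tensor:
    val = np.tanh(x.data)
    out = _node(val, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - val**2))

    out._backward = bwd
    return out


# -- structural ops ----------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gp)

    out._backward = bwd
    return out


def gather(x: Tensor, index: np.ndarray) -> Tensor:
    """Row gather: out[i] = x[index[i]]."""
    index = np.asarray(index, dtype=np.intp)
    out = _node(x.data[index], (x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, index, g)
            x._accumulate_owned(gx)

    out._backward = bwd
    return out


def segment_sum(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of x into `n_segments` buckets given per-row segment ids."""
    segments = np.asarray(segments, dtype=np.intp)
    data = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segments, x.data)
    out = _node(data, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[segments])

    out._backward = bwd
    return out


def segment_mean(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    counts = np.bincount(np.asarray(segments), minlength=n_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0).reshape((-1,) + (1,) * (x.data.ndim - 1))
    return segment_sum(x, segments, n_segments) * Tensor(1.0 / counts)


def segment_softmax(logits: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of a 1-D logit vector within each segment.

    The max-shift used for numerical stability is treated as a constant
    (its gradient contribution cancels exactly in the softmax).
    """
    segments = np.asarray(segments, dtype=np.intp)
    seg_max = np.full(n_segments, -np.inf)
    np.maximum.at(seg_max, segments, logits.data)
    shifted = logits + Tensor(-seg_max[segments])
    e = shifted.exp()
    denom = segment_sum(e, segments, n_segments)
    return e / gather(denom, segments)
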