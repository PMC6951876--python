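"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the BiLSTM-CRF taggers on CPU: elementwise
arithmetic with broadcasting, matmul, sigmoid/tanh/exp/log, axis sums,
concatenation/slicing, row gather/scatter and a numerically stable
log-sum-exp.  Graphs are built eagerly per example and freed after
``backward``; no broadcasting rules beyond numpy's own are implemented.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float)
        else:
            self.grad += grad

    # -- operations ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))
        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))
        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g, a=self, y=y):
            if a.requires_grad:
                a._accumulate(g * y * (1.0 - y))
        return Tensor._make(y, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)
        def backward(g, a=self, y=y):
            if a.requires_grad:
                a._accumulate(g * (1.0 - y * y))
        return Tensor._make(y, (self,), backward)

    def exp(self):
        y = np.exp(self.data)
        def backward(g, a=self, y=y):
            if a.requires_grad:
                a._accumulate(g * y)
        return Tensor._make(y, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)
        return Tensor._make(np.log(self.data), (self,), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.full(a.shape, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def reshape(self, *shape):
        old = self.shape
        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accumulate(g.reshape(old))
        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g.T)
        return Tensor._make(self.data.T, (self,), backward)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along *axis* (differentiable)."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                full = np.zeros(a.shape)
                full[idx] = g
                a._accumulate(full)
        return Tensor._make(self.data[idx], (self,), backward)

    def take_rows(self, indices: np.ndarray):
        """Row gather along axis 0 (embedding lookup); repeats allowed."""
        indices = np.asarray(indices, dtype=int)
        def backward(g, a=self, indices=indices):
            if a.requires_grad:
                full = np.zeros(a.shape)
                np.add.at(full, indices, g)
                a._accumulate(full)
        return Tensor._make(self.data[indices], (self,), backward)

    def gather(self, rows: np.ndarray, cols: np.ndarray):
        """Elementwise gather ``self[rows, cols]`` -> 1-D tensor."""
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        def backward(g, a=self, rows=rows, cols=cols):
            if a.requires_grad:
                full = np.zeros(a.shape)
                np.add.at(full, (rows, cols), g)
                a._accumulate(full)
        return Tensor._make(self.data[rows, cols], (self,), backward)

    def logsumexp(self, axis: int, keepdims: bool = False):
        """Numerically stable log-sum-exp along *axis*."""
        m = self.data.max(axis=axis, keepdims=True)  # treated as a constant
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        return out if keepdims else out.squeeze(axis)

    def squeeze(self, axis: int):
        old = self.shape
        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accumulate(g.reshape(old))
        return Tensor._make(np.squeeze(self.data, axis=axis), (self,), backward)

    # -- backprop ---------------------------------------------------------
    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (one node per timestep)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)
            # free interior graph state eagerly
            if node is not self:
                node._parents = ()
                node._backward = None


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def where_rows(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Rowwise select: rows of *a* where mask is 1, of *b* where 0.

    *mask* is a constant column vector ``(B, 1)``; used to freeze finished
    sequences inside batched recurrences.
    """
    m = Tensor(mask)
    return a * m + b * (1.0 - m)
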