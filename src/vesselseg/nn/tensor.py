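"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers the tensors it was computed from together with a closure that
propagates the output gradient to them.  ``backward()`` runs the closures in
reverse topological order.  The op set is exactly what the segmentation
network needs (dense/conv/transposed-conv layers, layer norm, GELU, softmax
attention with positional-bias gathers) — it is not a general framework.

All ops preserve the dtype of their inputs; the network runs in float32 by
default while unit-level numerical checks can feed float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


class Tensor:
    """An ndarray plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype if self.data.dtype.kind == "f" else np.float64)
        self.grad = self.grad + g

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
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
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------

    @staticmethod
    def _unbroadcast(g, shape):
        """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
        extra = g.ndim - len(shape)
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g.reshape(shape)

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(self._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(self._unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def roll(self, shift, axis):
        neg = tuple(-s for s in shift) if isinstance(shift, (tuple, list)) else -shift

        def backward(g):
            self._accum(np.roll(g, neg, axis=axis))

        return Tensor._make(np.roll(self.data, shift, axis=axis), (self,), backward)

    def pad(self, pad_width):
        slices = tuple(slice(lo, s + lo) for (lo, _), s in zip(pad_width, self.shape))

        def backward(g):
            self._accum(g[slices])

        return Tensor._make(np.pad(self.data, pad_width), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data, dtype=g.dtype)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, shape).astype(self.data.dtype, copy=False))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- matmul ---------------------------------------------------------------

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(self._unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(self._unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        # exact Gaussian-error-linear unit: x * Phi(x)
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        out_data = x * phi

        def backward(g):
            self._accum(g * (phi + x * pdf))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum((g - dot) * out_data)

        return Tensor._make(out_data, (self,), backward)


def concat(tensors, axis=-1):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), backward)


def take_pairs(logits_per_offset: Tensor, index: np.ndarray) -> Tensor:
    """Gather ``out[..., i, j] = a[..., i, index[i, j]]``.

    Used to turn per-(token, offset) positional terms into per-token-pair
    terms; ``index`` is the relative-position index table of a window.
    """
    a = logits_per_offset
    idx = np.broadcast_to(index, a.shape[:-2] + index.shape)
    out_data = np.take_along_axis(a.data, idx, axis=-1)

    def backward(g):
        ga = np.zeros_like(a.data, dtype=g.dtype)
        np.add.at(
            ga.reshape(-1, *a.shape[-2:]),
            (np.arange(int(np.prod(a.shape[:-2], dtype=int)))[:, None, None],
             np.arange(index.shape[0])[None, :, None],
             idx.reshape(-1, *index.shape)),
            g.reshape(-1, *index.shape),
        )
        a._accum(ga)

    return Tensor._make(out_data, (a,), backward)


def table_lookup(table: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows of ``table`` (n_entries, ...) by an integer index array."""
    out_data = table.data[index]

    def backward(g):
        gt = np.zeros_like(table.data, dtype=g.dtype)
        np.add.at(gt, index, g)
        table._accum(gt)

    return Tensor._make(out_data, (table,), backward)
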