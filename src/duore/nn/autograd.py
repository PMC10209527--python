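"""Compact reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operator set needed by the span-scoring,
relation-classification and prompt-conditioned heads: broadcasted arithmetic,
(batched) matmul, reductions, stable softmax/sigmoid, layer normalisation,
gather-style indexing and concatenation.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` over a topologically sorted graph.

All gradients are validated against central finite differences in the test
suite; keep any new operator under that regime.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        # float64 inputs keep their precision (finite-difference checks); all
        # else runs in float32 for speed
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()
        self._grad_owned = False

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        out._grad_owned = False
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        # grad is held by reference until a second contribution arrives;
        # only then is an owned copy materialised (most nodes have one child)
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(_matmul_grad_a(g, other.data))
            other._accum(_matmul_grad_b(g, self.data))

        return self._make(np.matmul(self.data, other.data), (self, other), bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accum(g.swapaxes(a, b))

        return self._make(self.data.swapaxes(a, b), (self,), bw)

    def __getitem__(self, idx):
        parts = idx if isinstance(idx, tuple) else (idx,)
        fancy = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def bw(g):
            full = np.zeros_like(self.data)
            if fancy:
                np.add.at(full, idx, g)  # repeated indices must accumulate
            else:
                full[idx] += g
            self._accum(full)

        return self._make(self.data[idx], (self,), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), bw)

    def layer_norm(self, eps: float = 1e-5):
        """Normalise the last axis to zero mean / unit variance (no affine)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc ** 2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out_data = xc * inv
        n = self.data.shape[-1]

        def bw(g):
            self._accum(
                inv * (g - g.mean(axis=-1, keepdims=True) - out_data * (g * out_data).mean(axis=-1, keepdims=True))
            )

        return self._make(out_data, (self,), bw)

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; identity when rate == 0."""
        if rate <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        mask = mask.astype(self.data.dtype)

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _matmul_grad_a(g: np.ndarray, b: np.ndarray) -> np.ndarray:
    if b.ndim == 1:
        return np.expand_dims(g, -1) * b
    return np.matmul(g, b.swapaxes(-1, -2))


def _matmul_grad_b(g: np.ndarray, a: np.ndarray) -> np.ndarray:
    if a.ndim == 1:
        return np.expand_dims(a, -1) * np.expand_dims(g, -2) if g.ndim else np.outer(a, g)
    return np.matmul(a.swapaxes(-1, -2), g)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)

    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    out.requires_grad = any(t.requires_grad for t in tensors)
    out._parents = tuple(t for t in tensors if t.requires_grad) if out.requires_grad else ()

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw if out.requires_grad else None
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    out.requires_grad = any(t.requires_grad for t in tensors)
    out._parents = tuple(t for t in tensors if t.requires_grad) if out.requires_grad else ()

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw if out.requires_grad else None
    return out
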