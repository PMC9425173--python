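"""Reverse-mode automatic differentiation over numpy arrays.

A minimal define-by-run tape: each op builds a :class:`Tensor` holding the
forward value and a closure that accumulates gradients into its parents.
Shapes broadcast like numpy; gradients are un-broadcast (summed) back to the
parent shape. All arithmetic is float64.

Only the primitives the summarization model needs are provided; each has a
hand-written backward that is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "embedding",
    "gather_last",
    "layer_norm",
    "masked_softmax",
    "scatter_sum",
]

_SQRT_2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Tensor:
    """A node in the autodiff graph: a value plus backward bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph traversal ----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        # never mutated in place, so sharing the incoming array is safe
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- convenience --------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast_matmul(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast_matmul(gb, other.data.shape))

        out._backward = backward
        return out

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def backward(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def backward(g):
            self._accumulate(g.transpose(inverse))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = backward
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        value = np.exp(self.data)
        out = Tensor(value, parents=(self,))

        def backward(g):
            self._accumulate(g * value)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(g):
            self._accumulate(g / self.data)

        out._backward = backward
        return out

    def tanh(self):
        value = np.tanh(self.data)
        out = Tensor(value, parents=(self,))

        def backward(g):
            self._accumulate(g * (1.0 - value**2))

        out._backward = backward
        return out

    def sigmoid(self):
        x = self.data
        value = np.empty_like(x)
        pos = x >= 0
        value[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        value[~pos] = ex / (1.0 + ex)
        out = Tensor(value, parents=(self,))

        def backward(g):
            self._accumulate(g * value * (1.0 - value))

        out._backward = backward
        return out

    def relu(self):
        value = np.maximum(self.data, 0.0)
        out = Tensor(value, parents=(self,))

        def backward(g):
            self._accumulate(g * (self.data > 0))

        out._backward = backward
        return out

    def gelu(self):
        # exact erf form: 0.5 x (1 + erf(x / sqrt 2))
        cdf = 0.5 * (1.0 + erf(self.data / _SQRT_2))
        out = Tensor(self.data * cdf, parents=(self,))

        def backward(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * self.data**2)
            self._accumulate(g * (cdf + self.data * pdf))

        out._backward = backward
        return out

    def clip_min(self, floor: float):
        """max(x, floor); gradient passes only where x > floor."""
        value = np.maximum(self.data, floor)
        out = Tensor(value, parents=(self,))

        def backward(g):
            self._accumulate(g * (self.data > floor))

        out._backward = backward
        return out

    def mask(self, mask: np.ndarray):
        """Zero out positions where ``mask`` is False (mask is constant)."""
        m = np.asarray(mask, dtype=bool)
        out = Tensor(np.where(m, self.data, 0.0), parents=(self,))

        def backward(g):
            self._accumulate(np.where(m, g, 0.0))

        out._backward = backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, dim in enumerate(shape):
        if dim == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _unbroadcast_matmul(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum matmul batch dims of ``grad`` back to ``shape``."""
    if grad.shape == shape:
        return grad
    return _unbroadcast(grad, shape)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])

    out._backward = backward
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward into the table."""
    ids = np.asarray(ids, dtype=np.int64)
    out = Tensor(table.data[ids], parents=(table,))

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids.ravel(), g.reshape(-1, table.data.shape[-1]))
        table._accumulate(full)

    out._backward = backward
    return out


def masked_softmax(logits: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` restricted to positions where ``mask`` is True.

    Masked positions get exactly zero probability. A row with no valid
    position yields all zeros (callers mask such rows out downstream).
    """
    m = np.broadcast_to(np.asarray(mask, dtype=bool), logits.data.shape)
    x = np.where(m, logits.data, -np.inf)
    xmax = np.max(x, axis=axis, keepdims=True)
    xmax = np.where(np.isfinite(xmax), xmax, 0.0)
    e = np.exp(x - xmax)
    e = np.where(m, e, 0.0)
    denom = e.sum(axis=axis, keepdims=True)
    p = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
    out = Tensor(p, parents=(logits,))

    def backward(g):
        inner = (g * p).sum(axis=axis, keepdims=True)
        logits._accumulate(p * (g - inner))

    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            dxhat = g * gamma.data
            mean_d = dxhat.mean(axis=-1, keepdims=True)
            mean_dx = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv_std * (dxhat - mean_d - xhat * mean_dx))

    out._backward = backward
    return out


def gather_last(x: Tensor, idx: np.ndarray) -> Tensor:
    """``out[..., j] = x[..., idx[..., j]]`` along the last axis."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(np.take_along_axis(x.data, idx, axis=-1), parents=(x,))

    def backward(g):
        full = np.zeros_like(x.data)
        k = x.data.shape[-1]
        flat = full.reshape(-1, k)
        fidx = np.broadcast_to(idx, g.shape).reshape(-1, g.shape[-1])
        rows = np.arange(flat.shape[0])[:, None]
        np.add.at(flat, (np.broadcast_to(rows, fidx.shape), fidx), g.reshape(fidx.shape))
        x._accumulate(full)

    out._backward = backward
    return out


def scatter_sum(weights: Tensor, ids: np.ndarray, size: int) -> Tensor:
    """Sum ``weights`` into ``size`` bins indexed by ``ids`` along the last axis.

    ``ids`` must broadcast to ``weights.shape``; duplicated ids accumulate.
    This is the copy-distribution primitive: attention mass on repeated source
    tokens adds up on the shared extended-vocabulary id.
    """
    ids = np.broadcast_to(np.asarray(ids, dtype=np.int64), weights.data.shape)
    s = weights.data.shape[-1]
    flat_w = weights.data.reshape(-1, s)
    flat_ids = ids.reshape(-1, s)
    flat_out = np.zeros((flat_w.shape[0], size))
    rows = np.arange(flat_w.shape[0])[:, None]
    np.add.at(flat_out, (np.broadcast_to(rows, flat_ids.shape), flat_ids), flat_w)
    out = Tensor(flat_out.reshape(weights.data.shape[:-1] + (size,)), parents=(weights,))

    def backward(g):
        flat_g = g.reshape(-1, size)
        gw = np.take_along_axis(flat_g, flat_ids, axis=1)
        weights._accumulate(gw.reshape(weights.data.shape))

    out._backward = backward
    return out
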