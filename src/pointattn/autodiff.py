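"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Channel-last tensors throughout. The engine records a tape of primitive
operations and back-propagates from a scalar loss; gradients accumulate in
``Tensor.grad`` as plain ndarrays. Dtype follows the input arrays, so the
same graph runs in float32 for training and float64 for finite-difference
gradient checks.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "neg", "div", "matmul", "power",
    "exp", "log", "sqrt", "sigmoid", "relu", "leaky_relu",
    "tsum", "tmean", "tmax", "concat", "reshape", "broadcast_to",
    "gather_groups", "edge_combine", "batch_norm_train", "log_softmax",
    "as_tensor",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        # gradients are never mutated in place, so sharing a view is safe
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Back-propagate from this tensor (scalar unless ``seed`` given)."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar output")
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(seed, dtype=self.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node._accumulate(g)
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if parent.requires_grad or parent._backward is not None:
                        if id(parent) in grads:
                            grads[id(parent)] = grads[id(parent)] + pg
                        else:
                            grads[id(parent)] = pg

    # -- operator sugar ---------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        # scalars adopt this tensor's dtype so float32 graphs stay float32
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.dtype))

    def __add__(self, other):
        return add(self, self._coerce(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, self._coerce(other))

    def __rsub__(self, other):
        return sub(self._coerce(other), self)

    def __mul__(self, other):
        return mul(self, self._coerce(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, self._coerce(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __pow__(self, p):
        return power(self, p)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], list] | None) -> Tensor:
    out = Tensor(data)
    track = any(p.requires_grad or p._backward is not None for p in parents)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- arithmetic -----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data
    return _make(data, (a, b), lambda g: [
        (a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))])


def sub(a: Tensor, b: Tensor) -> Tensor:
    data = a.data - b.data
    return _make(data, (a, b), lambda g: [
        (a, _unbroadcast(g, a.shape)), (b, _unbroadcast(-g, b.shape))])


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, (a,), lambda g: [(a, -g)])


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data
    return _make(data, (a, b), lambda g: [
        (a, _unbroadcast(g * b.data, a.shape)),
        (b, _unbroadcast(g * a.data, b.shape))])


def div(a: Tensor, b: Tensor) -> Tensor:
    data = a.data / b.data
    return _make(data, (a, b), lambda g: [
        (a, _unbroadcast(g / b.data, a.shape)),
        (b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape))])


def power(a: Tensor, p: float) -> Tensor:
    data = a.data ** p
    return _make(data, (a,), lambda g: [(a, g * p * a.data ** (p - 1))])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; supports (..., M, K) @ (K, N) and 2-D @ 2-D."""
    data = a.data @ b.data

    def backward(g: np.ndarray):
        if a.data.ndim == b.data.ndim == 2:
            return [(a, g @ b.data.T), (b, a.data.T @ g)]
        # stacked LHS against a plain matrix RHS
        ga = g @ b.data.T
        gb = a.data.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        return [(a, ga), (b, gb)]

    return _make(data, (a, b), backward)


# -- elementwise nonlinearities ------------------------------------------

def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)
    return _make(data, (a,), lambda g: [(a, g * data)])


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), lambda g: [(a, g / a.data)])


def sqrt(a: Tensor) -> Tensor:
    data = np.sqrt(a.data)
    return _make(data, (a,), lambda g: [(a, g / (2.0 * data))])


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-sided form
    x = a.data
    data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return _make(data, (a,), lambda g: [(a, g * data * (1.0 - data))])


def relu(a: Tensor) -> Tensor:
    data = np.maximum(a.data, 0)
    return _make(data, (a,), lambda g: [(a, g * (a.data > 0))])


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    data = np.where(a.data > 0, a.data, slope * a.data)
    one = a.dtype.type(1.0)
    neg = a.dtype.type(slope)
    return _make(data, (a,),
                 lambda g: [(a, g * np.where(a.data > 0, one, neg))])


# -- reductions -----------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: np.ndarray):
        if axis is None:
            return [(a, np.broadcast_to(g, a.shape).astype(a.dtype, copy=False))]
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return [(a, np.broadcast_to(gg, a.shape))]

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def tmax(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max over one axis; the gradient flows to the first maximum."""
    idx = np.expand_dims(a.data.argmax(axis=axis), axis)
    data = np.take_along_axis(a.data, idx, axis=axis)

    def backward(g: np.ndarray):
        gg = g if keepdims else np.expand_dims(g, axis)
        gx = np.zeros_like(a.data)
        np.put_along_axis(gx, idx, gg, axis=axis)
        return [(a, gx)]

    out_data = data if keepdims else np.squeeze(data, axis=axis)
    return _make(out_data, (a,), backward)


# -- shape ops ------------------------------------------------------------

def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    data = a.data.reshape(shape)
    return _make(data, (a,), lambda g: [(a, g.reshape(a.shape))])


def broadcast_to(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    data = np.broadcast_to(a.data, shape)
    return _make(data, (a,), lambda g: [(a, _unbroadcast(g, a.shape))])


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return _make(data, tensors, backward)


# -- structured ops -------------------------------------------------------

def gather_groups(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather per-point neighbor features.

    ``x`` is (B, N, C) and ``idx`` is an integer (B, N, k) table of point
    indices within each batch element; the result is (B, N, k, C).
    """
    idx = np.asarray(idx)
    B, N, C = x.shape
    k = idx.shape[-1]
    batch = np.arange(B)[:, None, None]
    data = x.data[batch, idx]

    def backward(g: np.ndarray):
        return [(x, _scatter_groups(g, idx, x.shape))]

    return _make(data, (x,), backward)


def _scatter_groups(grad: np.ndarray, idx: np.ndarray,
                    out_shape: tuple[int, ...]) -> np.ndarray:
    """Adjoint of the (B,N,k) group gather: scatter-add back to (B,N,C)."""
    B, N, C = out_shape
    k = idx.shape[-1]
    gx = np.zeros(out_shape, dtype=grad.dtype)
    flat_idx = (idx + (np.arange(B) * N)[:, None, None]).reshape(-1)
    np.add.at(gx.reshape(B * N, C), flat_idx, grad.reshape(B * N * k, C))
    return gx


def edge_combine(y: Tensor, z: Tensor, idx: np.ndarray) -> Tensor:
    """Fused EdgeConv linear lift: out[b,i,j] = y[b,idx[b,i,j]] - y[b,i] + z[b,i].

    With y = x @ W_diff and z = x @ W_center + b this equals the shared MLP
    applied to the edge pairs (x_j - x_i, x_i), but the dense products run
    per point instead of per edge.
    """
    idx = np.asarray(idx)
    B, N, C = y.shape
    batch = np.arange(B)[:, None, None]
    data = y.data[batch, idx] - y.data[:, :, None, :] + z.data[:, :, None, :]

    def backward(g: np.ndarray):
        gsum = g.sum(axis=2)
        gy = _scatter_groups(g, idx, y.shape) - gsum
        return [(y, gy), (z, gsum)]

    return _make(data, (y, z), backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor,
                     eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused training-mode batch norm over all axes but the last.

    Returns the normalized tensor plus the biased batch mean/variance per
    channel (for running-statistics updates).
    """
    axes = tuple(range(x.ndim - 1))
    mu = x.data.mean(axis=axes)
    var = x.data.var(axis=axes)
    inv = (1.0 / np.sqrt(var + eps)).astype(x.dtype)
    xhat = (x.data - mu) * inv
    data = xhat * gamma.data + beta.data

    def backward(g: np.ndarray):
        dbeta = g.sum(axis=axes)
        tmp = g * xhat
        dgamma = tmp.sum(axis=axes)
        # dx = inv * (dxhat - mean(dxhat) - xhat * mean(dxhat * xhat)),
        # with dxhat = g * gamma; computed in place to limit temporaries
        n = g.size // g.shape[-1]
        m2 = (dgamma * gamma.data) / n
        dx = g * (gamma.data * inv)
        m1 = dx.mean(axis=axes)
        np.multiply(xhat, m2 * inv, out=tmp)
        dx -= tmp
        dx -= m1
        return [(x, dx), (gamma, dgamma), (beta, dbeta)]

    out = _make(data, (x, gamma, beta), backward)
    return out, mu, var


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data
    m = x.max(axis=axis, keepdims=True)
    z = x - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    data = z - lse

    def backward(g: np.ndarray):
        soft = np.exp(data)
        return [(a, g - soft * g.sum(axis=axis, keepdims=True))]

    return _make(data, (a,), backward)
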