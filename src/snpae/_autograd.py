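"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the genotype autoencoder needs:
elementwise arithmetic, dense and 1-D convolutional contractions,
max-pooling, nearest-neighbour upsampling, reductions, and the
activation functions. Gradients propagate only into tensors that
(transitively) require them, so constant inputs cost nothing.

All arithmetic is float64; at the problem sizes this package targets
(thousands of markers, hundreds of samples) the numpy kernels dominate
and the graph overhead is negligible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "backward"]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._prev: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __pow__(self, e):
        return power(self, e)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, prev, backward_fn) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in prev))
    if out.requires_grad:
        out._prev = tuple(p for p in prev if p.requires_grad or p._prev)
        out._backward = backward_fn
    return out


def _acc(t: Tensor, g):
    if t.requires_grad or t._prev:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, s) in enumerate(zip(g.shape, shape)):
        if s == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def backward(out: Tensor):
    """Backpropagate d(out)/d(leaf) for every reachable gradient tensor."""
    topo, seen = [], set()

    def visit(t):
        if id(t) in seen or t._backward is None and not t.requires_grad:
            if id(t) not in seen:
                seen.add(id(t))
            return
        seen.add(id(t))
        for p in t._prev:
            visit(p)
        topo.append(t)

    visit(out)
    out.grad = np.ones_like(out.data)
    for t in reversed(topo):
        if t._backward is not None:
            t._backward(t)


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _t(a), _t(b)
    out = _make(a.data + b.data, (a, b), None)

    def bw(o):
        _acc(a, _unbroadcast(o.grad, a.data.shape))
        _acc(b, _unbroadcast(o.grad, b.data.shape))

    out._backward = bw if out.requires_grad else None
    return out


def mul(a, b):
    a, b = _t(a), _t(b)
    out = _make(a.data * b.data, (a, b), None)

    def bw(o):
        _acc(a, _unbroadcast(o.grad * b.data, a.data.shape))
        _acc(b, _unbroadcast(o.grad * a.data, b.data.shape))

    out._backward = bw if out.requires_grad else None
    return out


def power(a, e: float):
    a = _t(a)
    out = _make(a.data ** e, (a,), None)

    def bw(o):
        _acc(a, o.grad * e * a.data ** (e - 1.0))

    out._backward = bw if out.requires_grad else None
    return out


def exp(a):
    a = _t(a)
    y = np.exp(a.data)
    out = _make(y, (a,), None)

    def bw(o):
        _acc(a, o.grad * y)

    out._backward = bw if out.requires_grad else None
    return out


def log(a):
    a = _t(a)
    out = _make(np.log(a.data), (a,), None)

    def bw(o):
        _acc(a, o.grad / a.data)

    out._backward = bw if out.requires_grad else None
    return out


def sqrt(a):
    return power(a, 0.5)


def clip_min(a, floor: float):
    """max(a, floor); gradient is 1 where a > floor, else 0."""
    a = _t(a)
    out = _make(np.maximum(a.data, floor), (a,), None)

    def bw(o):
        _acc(a, o.grad * (a.data > floor))

    out._backward = bw if out.requires_grad else None
    return out


def elu(a):
    a = _t(a)
    neg = np.exp(np.minimum(a.data, 0.0)) - 1.0
    y = np.where(a.data > 0.0, a.data, neg)
    out = _make(y, (a,), None)

    def bw(o):
        _acc(a, o.grad * np.where(a.data > 0.0, 1.0, neg + 1.0))

    out._backward = bw if out.requires_grad else None
    return out


def sigmoid(a):
    a = _t(a)
    y = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(y, (a,), None)

    def bw(o):
        _acc(a, o.grad * y * (1.0 - y))

    out._backward = bw if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = _t(a)
    out = _make(a.data.reshape(shape), (a,), None)

    def bw(o):
        _acc(a, o.grad.reshape(a.data.shape))

    out._backward = bw if out.requires_grad else None
    return out


def broadcast_to(a, shape):
    a = _t(a)
    out = _make(np.broadcast_to(a.data, shape), (a,), None)

    def bw(o):
        _acc(a, _unbroadcast(o.grad, a.data.shape))

    out._backward = bw if out.requires_grad else None
    return out


def concat(tensors, axis: int = -1):
    ts = [_t(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in ts], axis=axis), tuple(ts), None)
    sizes = [t.data.shape[axis] for t in ts]
    offs = np.cumsum([0] + sizes)

    def bw(o):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            idx = [slice(None)] * o.grad.ndim
            idx[axis] = slice(lo, hi)
            _acc(t, o.grad[tuple(idx)])

    out._backward = bw if out.requires_grad else None
    return out


def pad_axis1(a, left: int, right: int):
    """Zero-pad along the spatial (second) axis of a (B, L, C) tensor."""
    a = _t(a)
    if left == 0 and right == 0:
        return a
    out = _make(np.pad(a.data, ((0, 0), (left, right), (0, 0))), (a,), None)
    L = a.data.shape[1]

    def bw(o):
        _acc(a, o.grad[:, left:left + L, :])

    out._backward = bw if out.requires_grad else None
    return out


def crop_axis1(a, start: int, length: int):
    a = _t(a)
    out = _make(a.data[:, start:start + length], (a,), None)

    def bw(o):
        g = np.zeros_like(a.data)
        g[:, start:start + length] = o.grad
        _acc(a, g)

    out._backward = bw if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = _t(a)
    out = _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), None)

    def bw(o):
        g = o.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _acc(a, np.broadcast_to(g, a.data.shape).copy())

    out._backward = bw if out.requires_grad else None
    return out


def tmean(a, axis=None, keepdims=False):
    a = _t(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# ---------------------------------------------------------------------------
# dense / convolutional contractions
# ---------------------------------------------------------------------------

def dense(x, w, b=None):
    """x (..., n) @ w (n, m) [+ b (m,)]."""
    x, w = _t(x), _t(w)
    y = x.data @ w.data
    prev = [x, w]
    if b is not None:
        b = _t(b)
        y = y + b.data
        prev.append(b)
    out = _make(y, tuple(prev), None)
    n, m = w.data.shape

    def bw(o):
        g = o.grad
        _acc(x, g @ w.data.T)
        _acc(w, x.data.reshape(-1, n).T @ g.reshape(-1, m))
        if b is not None:
            _acc(b, g.reshape(-1, m).sum(axis=0))

    out._backward = bw if out.requires_grad else None
    return out


def conv1d_same(x, w, b):
    """Stride-1, zero-padded ("same") 1-D convolution.

    x: (B, L, Cin); w: (K, Cin, F) with K odd; b: (F,).  Output (B, L, F).
    """
    x, w, b = _t(x), _t(w), _t(b)
    K, Cin, F = w.data.shape
    if K % 2 != 1:
        raise ValueError("conv1d_same requires an odd kernel size")
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    # (B, L, Cin, K) view
    patches = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    y = np.einsum("blck,kcf->blf", patches, w.data, optimize=True) + b.data
    out = _make(y, (x, w, b), None)
    B, L, _ = x.data.shape

    def bw(o):
        g = o.grad  # (B, L, F)
        _acc(w, np.einsum("blf,blck->kcf", g, patches, optimize=True))
        _acc(b, g.sum(axis=(0, 1)))
        if x.requires_grad or x._prev:
            gx_pad = np.zeros_like(xp)
            for k in range(K):
                # contribution of kernel tap k lands at offset k in padded x
                gx_pad[:, k:k + L, :] += g @ w.data[k].T
            _acc(x, gx_pad[:, pad:pad + L, :])

    out._backward = bw if out.requires_grad else None
    return out


def maxpool1d(x, factor: int):
    """Non-overlapping max pooling along axis 1; L must divide by factor."""
    x = _t(x)
    B, L, C = x.data.shape
    if L % factor != 0:
        raise ValueError(f"spatial length {L} not divisible by pool factor {factor}")
    xr = x.data.reshape(B, L // factor, factor, C)
    idx = xr.argmax(axis=2)
    y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    out = _make(y, (x,), None)

    def bw(o):
        g = np.zeros_like(xr)
        np.put_along_axis(g, idx[:, :, None, :], o.grad[:, :, None, :], axis=2)
        _acc(x, g.reshape(B, L, C))

    out._backward = bw if out.requires_grad else None
    return out


def upsample1d(x, factor: int):
    """Nearest-neighbour upsampling: repeat each position `factor` times."""
    x = _t(x)
    B, L, C = x.data.shape
    out = _make(np.repeat(x.data, factor, axis=1), (x,), None)

    def bw(o):
        _acc(x, o.grad.reshape(B, L, factor, C).sum(axis=2))

    out._backward = bw if out.requires_grad else None
    return out


def softmax_lastdim(x):
    """Numerically stable softmax over the last axis."""
    x = _t(x)
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=-1, keepdims=True)
    out = _make(y, (x,), None)

    def bw(o):
        dot = (o.grad * y).sum(axis=-1, keepdims=True)
        _acc(x, y * (o.grad - dot))

    out._backward = bw if out.requires_grad else None
    return out
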