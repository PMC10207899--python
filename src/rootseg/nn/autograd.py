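"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides the small set of differentiable operations the segmentation
network needs: broadcasting arithmetic, (batched) matmul, 2-D convolution
via im2col, separable bilinear/nearest resizing, activations, reductions
and shape ops.  Tensors are float32 NCHW throughout the network code.

Gradient tracking is a global switch (`no_grad`) so inference runs without
building a graph.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (many conv layers)
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph as we go
                if not node.requires_grad:
                    node.grad = None
                node._backward = None
                node._parents = ()

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- operator sugar ------------------------------------------------
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
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _node(out, (a,), backward)


def texp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out)

    return _node(out, (a,), backward)


def tlog(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _node(out, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _node(out, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # overflow-safe: exponentiate the non-positive branch only
    x = a.data
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)

    def backward(g):
        a._accumulate(g * out * (1.0 - out))

    return _node(out, (a,), backward)


def clamp(a, lo: float, hi: float) -> Tensor:
    """Clip to [lo, hi]; gradient is passed only inside the interval."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)

    def backward(g):
        a._accumulate(g * ((a.data >= lo) & (a.data <= hi)))

    return _node(out, (a,), backward)


# ---------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return _node(out, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in np.atleast_1d(axis)])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape
    out = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(old))

    return _node(out, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = a.data.transpose(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _node(out, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out = np.concatenate([t.data for t in ts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _node(out, ts, backward)


# ---------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    """Matrix product with NumPy batch broadcasting on leading dims."""
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def backward(g):
        if a.data.ndim == 1 or b.data.ndim == 1:
            raise NotImplementedError("1-D matmul operands unsupported")
        ga = np.matmul(g, b.data.swapaxes(-1, -2))
        gb = np.matmul(a.data.swapaxes(-1, -2), g)
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _node(out, (a, b), backward)


# ---------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int,
            pad: int) -> tuple[np.ndarray, int, int]:
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((b, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * ho:stride,
                                 j:j + stride * wo:stride]
    return cols.reshape(b, c * kh * kw, ho * wo), ho, wo


def _col2im(gcols: np.ndarray, xshape: tuple[int, ...], kh: int, kw: int,
            stride: int, pad: int) -> np.ndarray:
    b, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    gcols = gcols.reshape(b, c, kh, kw, ho, wo)
    gx = np.zeros((b, c, hp, wp), dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + stride * ho:stride,
               j:j + stride * wo:stride] += gcols[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:hp - pad, pad:wp - pad]
    return gx


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW; weight (Cout, Cin, kh, kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    co, ci, kh, kw = weight.data.shape
    if x.data.shape[1] != ci:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]} channels, "
            f"weight expects {ci}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(co, -1)
    out = np.matmul(wmat[None], cols).reshape(x.data.shape[0], co, ho, wo)
    if bias is not None:
        bias = as_tensor(bias)
        out += bias.data.reshape(1, co, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        b = g.shape[0]
        gmat = g.reshape(b, co, ho * wo)
        gw = np.einsum("bol,bkl->ok", gmat, cols, optimize=True)
        weight._accumulate(gw.reshape(weight.data.shape))
        gcols = np.matmul(wmat.T[None], gmat)
        x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, padding))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return _node(out, parents, backward)


# ---------------------------------------------------------------------
# resizing (separable row/column interpolation matrices)
# ---------------------------------------------------------------------

def _resize_matrix(n_in: int, n_out: int, mode: str) -> np.ndarray:
    """Row-stochastic (n_out, n_in) 1-D resampling operator.

    Bilinear uses half-pixel centers (align_corners=False convention);
    nearest picks the floor of the mapped center.
    """
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    centers = (np.arange(n_out) + 0.5) * scale - 0.5
    if mode == "nearest":
        idx = np.clip(np.floor((np.arange(n_out) + 0.5) * scale), 0,
                      n_in - 1).astype(int)
        m[np.arange(n_out), idx] = 1.0
        return m
    lo = np.floor(centers).astype(int)
    frac = (centers - lo).astype(np.float32)
    lo0 = np.clip(lo, 0, n_in - 1)
    lo1 = np.clip(lo + 1, 0, n_in - 1)
    np.add.at(m, (np.arange(n_out), lo0), 1.0 - frac)
    np.add.at(m, (np.arange(n_out), lo1), frac)
    return m


def resize2d(x, out_hw: tuple[int, int], mode: str = "bilinear") -> Tensor:
    """Resize (B,C,H,W) to out_hw with bilinear or nearest interpolation."""
    x = as_tensor(x)
    h, w = x.data.shape[-2:]
    ho, wo = out_hw
    ry = _resize_matrix(h, ho, mode)          # (Ho, H)
    rx = _resize_matrix(w, wo, mode)          # (Wo, W)
    out = np.matmul(np.matmul(ry, x.data), rx.T)

    def backward(g):
        x._accumulate(np.matmul(np.matmul(ry.T, g), rx))

    return _node(out, (x,), backward)


# ---------------------------------------------------------------------
# softmax family
# ---------------------------------------------------------------------

def softmax(x, axis: int) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate(out * (g - dot))

    return _node(out, (x,), backward)


def log_softmax(x, axis: int) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse

    def backward(g):
        p = np.exp(out)
        x._accumulate(g - p * g.sum(axis=axis, keepdims=True))

    return _node(out, (x,), backward)
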