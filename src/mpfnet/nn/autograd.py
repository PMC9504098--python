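"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ``ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` replays the tape in reverse
topological order and accumulates gradients.  Only the operations the
network architectures in this package need are provided — dense and
batched matrix products, 2-D convolution, elementwise nonlinearities,
reductions, shape manipulation and resampling — each with a hand-written
vector-Jacobian product.  Everything is double precision so that
finite-difference gradient checks are meaningful to ~1e-7.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _special

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "mul", "matmul", "concat", "relu", "gelu", "sigmoid", "tanh",
    "exp", "log", "softmax", "reshape", "transpose", "pad2d", "conv2d",
    "upsample_nearest2d", "upsample_bilinear2d", "reduce_sum", "reduce_mean",
    "reduce_max", "power", "sqrt",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -------------------------------------------------
    @staticmethod
    def _from_op(data: np.ndarray, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep tapes would overflow recursion
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # method aliases used throughout the model code
    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return reduce_max(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return Tensor._from_op(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return Tensor._from_op(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor._from_op(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0.0))

    return Tensor._from_op(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = _special.expit(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._from_op(out_data, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out_data * out_data))

    return Tensor._from_op(out_data, (a,), backward)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact Gaussian-error-linear unit: x * Phi(x)."""
    a = as_tensor(a)
    cdf = 0.5 * (1.0 + _special.erf(a.data * _INV_SQRT2))
    out_data = a.data * cdf

    def backward(g):
        if a.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
            a._accumulate(g * (cdf + a.data * pdf))

    return Tensor._from_op(out_data, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return Tensor._from_op(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _norm_axes(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(ax % ndim for ax in axis)


def reduce_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    axes = _norm_axes(axis, a.ndim)
    out_data = a.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if not keepdims:
                g = np.expand_dims(g, axes)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return Tensor._from_op(out_data, (a,), backward)


def reduce_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    axes = _norm_axes(axis, a.ndim)
    n = int(np.prod([a.data.shape[ax] for ax in axes]))
    out_data = a.data.mean(axis=axes, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            if not keepdims:
                g = np.expand_dims(g, axes)
            a._accumulate(np.broadcast_to(g, a.data.shape) / n)

    return Tensor._from_op(out_data, (a,), backward)


def reduce_max(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    axes = _norm_axes(axis, a.ndim)
    out_data = a.data.max(axis=axes, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            full = a.data.max(axis=axes, keepdims=True)
            mask = (a.data == full)
            # ties share the gradient equally, keeping the VJP symmetric
            mask = mask / mask.sum(axis=axes, keepdims=True)
            gk = g if keepdims else np.expand_dims(g, axes)
            a._accumulate(mask * gk)

    return Tensor._from_op(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return Tensor._from_op(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = a.data.transpose(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return Tensor._from_op(out_data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def pad2d(a, pad: int) -> Tensor:
    """Zero-pad the two trailing (spatial) axes of an NCHW tensor."""
    a = as_tensor(a)
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    out_data = np.pad(a.data, width)

    def backward(g):
        if a.requires_grad:
            sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
            a._accumulate(g[sl])

    return Tensor._from_op(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor._from_op(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# convolution and resampling
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of an NCHW input with OIHW filters.

    Implemented with ``sliding_window_view`` + einsum on the forward pass
    and an explicit kernel-offset scatter on the backward pass.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    kh, kw = w.data.shape[2], w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # N,C,OH,OW,kh,kw
    out_data = np.einsum("nchwij,ocij->nohw", windows, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    oh, ow = out_data.shape[2], out_data.shape[3]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if w.requires_grad:
            w._accumulate(np.einsum("nohw,nchwij->ocij", g, windows, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    contrib = np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
                    gxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += contrib
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._from_op(out_data, parents, backward)


def upsample_nearest2d(a, scale: int = 2) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.repeat(scale, axis=-2).repeat(scale, axis=-1)

    def backward(g):
        if a.requires_grad:
            n, c, h, w = a.data.shape
            gr = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
            a._accumulate(gr)

    return Tensor._from_op(out_data, (a,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic linear-interpolation matrix (align_corners=False)."""
    A = np.zeros((n_out, n_in))
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        A[i, lo_c] += 1.0 - frac
        A[i, hi_c] += frac
    return A


def upsample_bilinear2d(a, scale: int) -> Tensor:
    """Bilinear upsampling expressed as two interpolation matmuls."""
    a = as_tensor(a)
    h, w = a.data.shape[-2], a.data.shape[-1]
    Ah = _interp_matrix(h * scale, h)
    Aw = _interp_matrix(w * scale, w)
    out_data = np.einsum("pi,ncij,qj->ncpq", Ah, a.data, Aw, optimize=True)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.einsum("pi,ncpq,qj->ncij", Ah, g, Aw, optimize=True))

    return Tensor._from_op(out_data, (a,), backward)
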