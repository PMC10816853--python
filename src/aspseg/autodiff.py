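"""Compact reverse-mode automatic differentiation on NumPy arrays.

Every segmentation loss in this package must expose gradients with respect
to the predicted probability mask (for training) and, for the learned
weighting module, with respect to its parameters.  This module provides a
small define-by-run tape: a :class:`Tensor` wraps an ``ndarray``, records
the operations applied to it, and :meth:`Tensor.backward` accumulates
gradients by reverse topological traversal.

Only the primitives actually used by the package are implemented:
elementwise arithmetic, ``log``/``exp``/``sigmoid``/``relu``/``clip``,
reductions, broadcasting-aware binary ops, ``matmul``, 2-D convolution via
im2col, average pooling, nearest-neighbour upsampling, channel
concatenation, patch extraction (for regional losses), matrix inverse and
log-determinant.  Arrays are used as-is (float64 in the loss oracles,
float32 in the training harness); gradients inherit the data dtype.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "avg_pool2d",
    "max_pool2d",
    "upsample_nearest",
    "extract_patches",
    "matrix_inverse",
    "logdet",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float) if not isinstance(data, np.ndarray) else data
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
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
        grad = grad.astype(self.data.dtype, copy=False)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._from_op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._from_op(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)
        out_data = a.data ** p

        def backward(g):
            if a.requires_grad:
                # d/dx x^p = p x^(p-1); safe at x=0 for p >= 1, and for
                # 0 < p < 1 the subgradient at 0 is clipped to 0.
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = p * a.data ** (p - 1.0)
                d = np.where(np.isfinite(d), d, 0.0)
                a._accum(g * d)

        return Tensor._from_op(out_data, (a,), backward)

    # -- elementwise functions ------------------------------------------------
    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._from_op(np.log(a.data), (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._from_op(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._from_op(a.data * mask, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the interior only."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def backward(g):
            a._accum(g * mask)

        return Tensor._from_op(np.clip(a.data, lo, hi), (a,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._from_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            a._accum(g.reshape(a.shape))

        return Tensor._from_op(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._from_op(a.data.transpose(axes), (a,), backward)

    @property
    def T(self):
        return self.transpose(*reversed(range(self.ndim)))

    def __getitem__(self, key):
        a = self
        keys = key if isinstance(key, tuple) else (key,)
        basic = all(isinstance(k, (int, np.integer, slice)) or k is Ellipsis
                    for k in keys)

        def backward(g):
            full = np.zeros_like(a.data)
            if basic:  # basic indexing never aliases: direct accumulate is safe
                full[key] += g
            else:
                np.add.at(full, key, g)
            a._accum(full)

        return Tensor._from_op(a.data[key], (a,), backward)

    # -- linear algebra -------------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._from_op(a.data @ b.data, (a, b), backward)


def as_tensor(x) -> Tensor:
    """Wrap ``x`` in a non-differentiable :class:`Tensor` if needed."""
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# structural / convolutional primitives
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._from_op(data, tensors, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation over NCHW batches (im2col + GEMM)."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, kernel {Cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    L = Ho * Wo
    wmat = w.data.reshape(Cout, C * kh * kw)
    if kh == kw == 1 and stride == 1:
        cols = xp.reshape(N, C, L)
    else:
        view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        # (N, C, Ho, Wo, kh, kw) -> (N, C, kh, kw, Ho, Wo): the spatial dims stay
        # innermost so the im2col copy runs over long contiguous stretches
        cols = np.ascontiguousarray(view.transpose(0, 1, 4, 5, 2, 3)) \
            .reshape(N, C * kh * kw, L)
    out = np.matmul(wmat[None], cols).reshape(N, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)

    parents = (x, w) + ((b,) if b is not None else ())

    def backward(g):
        gl = g.reshape(N, Cout, L)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.matmul(gl, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            dcols = np.matmul(wmat.T[None], gl)                    # (N, CKK, L)
            if kh == kw == 1 and stride == 1:
                dxp = dcols.reshape(xp.shape)
                dxp = dxp.copy() if dxp.base is not None else dxp
            else:
                dview = dcols.reshape(N, C, kh, kw, Ho, Wo)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                            dview[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._from_op(out, parents, backward)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k×k average pooling (NCHW or plain 2-D input)."""
    x = as_tensor(x)
    squeeze = x.ndim == 2
    data = x.data[None, None] if squeeze else x.data
    N, C, H, W = data.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: size {(H, W)} not divisible by {k}")
    out = data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def backward(g):
        gg = g[None, None] if squeeze else g
        full = np.repeat(np.repeat(gg, k, axis=2), k, axis=3) / (k * k)
        x._accum(full[0, 0] if squeeze else full)

    return Tensor._from_op(out[0, 0] if squeeze else out, (x,), backward)


def max_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k×k max pooling of a plain 2-D map."""
    x = as_tensor(x)
    H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"max_pool2d: size {(H, W)} not divisible by {k}")
    Ho, Wo = H // k, W // k
    blocks = x.data.reshape(Ho, k, Wo, k).transpose(0, 2, 1, 3).reshape(Ho, Wo, k * k)
    idx = blocks.argmax(axis=2)
    out = np.take_along_axis(blocks, idx[..., None], axis=2)[..., 0]

    def backward(g):
        dblocks = np.zeros((Ho, Wo, k * k), dtype=x.data.dtype)
        np.put_along_axis(dblocks, idx[..., None], g[..., None], axis=2)
        dx = dblocks.reshape(Ho, Wo, k, k).transpose(0, 2, 1, 3).reshape(H, W)
        x._accum(dx)

    return Tensor._from_op(out, (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def backward(g):
        gg = g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
        x._accum(gg)

    return Tensor._from_op(out, (x,), backward)


def extract_patches(x: Tensor, size: int, stride: int = 1) -> Tensor:
    """All ``size``×``size`` patches of a 2-D map as a (size², L) matrix.

    Column ``l`` holds the patch around the l-th valid centre, flattened
    row-major — the multi-dimensional "points" of regional losses.
    """
    x = as_tensor(x)
    H, W = x.shape
    Ho = (H - size) // stride + 1
    Wo = (W - size) // stride + 1
    view = sliding_window_view(x.data, (size, size))[::stride, ::stride]
    cols = np.ascontiguousarray(view).reshape(Ho * Wo, size * size).T

    def backward(g):
        gview = g.T.reshape(Ho, Wo, size, size)
        dx = np.zeros_like(x.data)
        for i in range(size):
            for j in range(size):
                dx[i:i + stride * Ho:stride, j:j + stride * Wo:stride] += gview[:, :, i, j]
        x._accum(dx)

    return Tensor._from_op(cols, (x,), backward)


def matrix_inverse(x: Tensor) -> Tensor:
    x = as_tensor(x)
    inv = np.linalg.inv(x.data)

    def backward(g):
        x._accum(-(inv.T @ g @ inv.T))

    return Tensor._from_op(inv, (x,), backward)


def logdet(x: Tensor) -> Tensor:
    """log|det X| of a square matrix (scalar output)."""
    x = as_tensor(x)
    sign, val = np.linalg.slogdet(x.data)
    if sign <= 0:
        raise np.linalg.LinAlgError("logdet: matrix is not positive-definite")
    inv_t = np.linalg.inv(x.data).T

    def backward(g):
        x._accum(float(g) * inv_t)

    return Tensor._from_op(np.asarray(val), (x,), backward)
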