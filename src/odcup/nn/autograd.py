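"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: every operation returns a
:class:`Tensor` that remembers its parents and a closure computing the
vector-Jacobian product. Convolutions are evaluated as a sum of
``kh * kw`` BLAS matrix products over shifted input slices, which keeps
peak memory far below an explicit im2col buffer at 640-pixel resolution.

Only the operations the segmentation network needs are implemented;
shapes follow the NCHW convention with an explicit batch axis.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
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
    """An n-d array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        self.requires_grad = requires_grad
        self.grad = None
        self._backward = None
        self._prev = ()

    # -- basic protocol -------------------------------------------------
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def reshape(self, *shape):
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    in_shape = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(in_shape))

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-sided formulation
    x = a.data
    out_data = np.empty_like(x)
    pos = x >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    x = a.data
    out_data = np.where(x >= 0, x, slope * x)

    def backward(g):
        a._accumulate(g * np.where(x >= 0, 1.0, slope).astype(x.dtype))

    return _make(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    x = a.data
    out_data = np.maximum(x, 0)

    def backward(g):
        a._accumulate(g * (x > 0).astype(x.dtype))

    return _make(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def mean(a: Tensor, axes, keepdims: bool = False) -> Tensor:
    axes = tuple(axes)
    out_data = a.data.mean(axis=axes, keepdims=keepdims)
    count = np.prod([a.data.shape[i] for i in axes])

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g / count, a.data.shape))

    return _make(out_data, (a,), backward)


def spatial_max(a: Tensor) -> Tensor:
    """Global max over (H, W): (N,C,H,W) -> (N,C,1,1)."""
    n, c, h, w = a.data.shape
    flat = a.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, idx[:, :, None], axis=2).reshape(n, c, 1, 1)

    def backward(g):
        dflat = np.zeros((n, c, h * w), dtype=a.data.dtype)
        np.put_along_axis(dflat, idx[:, :, None], g.reshape(n, c, 1), axis=2)
        a._accumulate(dflat.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def channel_max(a: Tensor) -> Tensor:
    """Max over the channel axis: (N,C,H,W) -> (N,1,H,W)."""
    idx = a.data.argmax(axis=1)
    out_data = np.take_along_axis(a.data, idx[:, None], axis=1)

    def backward(g):
        d = np.zeros_like(a.data)
        np.put_along_axis(d, idx[:, None], g, axis=1)
        a._accumulate(d)

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 cross-correlation, NCHW input, (Cout,Cin,kh,kw) weight."""
    n, ci, h, wd = x.data.shape
    co, ci_w, kh, kw = w.data.shape
    if ci != ci_w:
        raise ValueError(f"conv2d channel mismatch: input {ci}, weight {ci_w}")
    ho, wo = h + 2 * padding - kh + 1, wd + 2 * padding - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d output would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))

    acc = np.zeros((n, ho, wo, co), dtype=x.data.dtype)
    for di in range(kh):
        for dj in range(kw):
            patch = xp[:, :, di:di + ho, dj:dj + wo]
            # (N,Ci,Ho,Wo) x (Co,Ci) -> (N,Ho,Wo,Co)
            acc += np.tensordot(patch, w.data[:, :, di, dj], axes=([1], [1]))
    out_data = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data.reshape(1, co, 1, 1)

    def backward(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    # (N,Co,Ho,Wo) x (Co,Ci) -> (N,Ho,Wo,Ci)
                    d = np.tensordot(g, w.data[:, :, di, dj], axes=([1], [0]))
                    dxp[:, :, di:di + ho, dj:dj + wo] += d.transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for di in range(kh):
                for dj in range(kw):
                    patch = xp[:, :, di:di + ho, dj:dj + wo]
                    dw[:, :, di, dj] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def conv_transpose2d_x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact x2 upsampling).

    Weight shape (Cin, Cout, 2, 2); output pixels do not overlap, so the
    operation is a single tensor contraction plus an interleaving reshape.
    """
    n, ci, h, wd = x.data.shape
    ci_w, co, kh, kw = w.data.shape
    if ci != ci_w:
        raise ValueError(f"conv_transpose2d channel mismatch: {ci} vs {ci_w}")
    if (kh, kw) != (2, 2):
        raise ValueError("only kernel 2, stride 2 supported")
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N,H,W,Co,2,2)
    out_data = np.ascontiguousarray(
        t.transpose(0, 3, 1, 4, 2, 5).reshape(n, co, 2 * h, 2 * wd)
    )
    if b is not None:
        out_data += b.data.reshape(1, co, 1, 1)

    def backward(g):
        g6 = g.reshape(n, co, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)  # N,H,W,Co,2,2
        if x.requires_grad:
            dx = np.tensordot(g6, w.data, axes=([3, 4, 5], [1, 2, 3]))  # N,H,W,Ci
            x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))
        if w.requires_grad:
            dw = np.tensordot(x.data, g6, axes=([0, 2, 3], [0, 1, 2]))  # Ci,Co,2,2
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling; with k=3, s=2, p=1 an even side is halved exactly."""
    n, c, h, wd = x.data.shape
    neg = np.finfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    idx = flat.argmax(axis=4)
    out_data = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]

    def backward(g):
        ii, jj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = ii[None, None] * stride - padding + idx // kernel
        cols = jj[None, None] * stride - padding + idx % kernel
        dx = np.zeros_like(x.data)
        nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        nn = nn[:, :, None, None]
        cc = cc[:, :, None, None]
        np.add.at(dx, (np.broadcast_to(nn, idx.shape), np.broadcast_to(cc, idx.shape),
                       rows, cols), g)
        x._accumulate(dx)

    return _make(np.ascontiguousarray(out_data), (x,), backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    In training mode the running statistics are updated in place with the
    unbiased batch variance, mirroring the usual deep-learning convention.
    """
    n, c, h, wd = x.data.shape
    if training:
        m = n * h * wd
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data.reshape(1, c, 1, 1) * invstd.reshape(1, c, 1, 1)
            if training:
                m = n * h * wd
                sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = gs * (g - sum_g / m - xhat * sum_gx / m)
            else:
                dx = gs * g
            x._accumulate(dx)

    return _make(out_data, (x, gamma, beta), backward)


def bce_loss_op(p: Tensor, t: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy over every element of `p`.

    Probabilities are clipped to [eps, 1-eps] before taking logs; where the
    clip is active the gradient is zero (the clip is flat there).
    """
    t = np.asarray(t, dtype=p.data.dtype)
    if t.shape != p.data.shape:
        raise ValueError(f"shape mismatch: prediction {p.data.shape}, target {t.shape}")
    pc = np.clip(p.data, eps, 1.0 - eps)
    n = p.data.size
    out_data = np.asarray(
        -(t * np.log(pc) + (1.0 - t) * np.log1p(-pc)).sum() / n, dtype=p.data.dtype
    )

    def backward(g):
        inside = (p.data > eps) & (p.data < 1.0 - eps)
        dp = np.where(inside, (pc - t) / (pc * (1.0 - pc)) / n, 0.0)
        p._accumulate(g * dp.astype(p.data.dtype))

    return _make(out_data, (p,), backward)
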