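"""Reverse-mode automatic differentiation over numpy arrays.

A small define-by-run tape: each operation returns a :class:`Tensor` holding
the result and a closure that routes the upstream gradient to its parents.
Only the operations needed for 2-D convolutional encoder–decoder networks are
provided (convolution, pooling, normalization, pointwise nonlinearities,
concatenation, and fused segmentation losses).  Convolutions run as
im2col + BLAS matrix products; everything supports stride-1 kernels with
arbitrary (possibly asymmetric) zero padding and dilation, which is all the
architectures here require.  Spatial downsampling is done by pooling and
upsampling by zero-insertion followed by a convolution, so transposed
convolutions differentiate for free.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "mul",
    "concat",
    "relu",
    "sigmoid",
    "conv2d",
    "zero_insert2d",
    "max_pool2d",
    "avg_pool2d",
    "nearest_upsample2d",
    "batch_norm2d",
    "bce_loss",
    "dice_loss",
    "mean",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep U-Nets overflow recursion limits
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go so im2col buffers are reclaimed
            node._backward = None
            node._parents = ()

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# pointwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g, a.shape))
        b.accumulate(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a.accumulate(_unbroadcast(g * b.data, a.shape))
        b.accumulate(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x.accumulate(g * mask)

    return _node(np.where(mask, x.data, 0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable piecewise logistic
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out[~pos] = ex / (1.0 + ex)

    def backward(g):
        x.accumulate(g * out * (1.0 - out))

    return _node(out, (x,), backward)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        x.accumulate(np.full_like(x.data, g / n))

    return _node(np.asarray(x.data.mean(), dtype=x.dtype), (x,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, dilation: int):
    """(B,C,Hp,Wp) -> columns (B*Ho*Wo, C*k*k) for a stride-1 correlation."""
    ke = dilation * (k - 1) + 1
    win = sliding_window_view(xp, (ke, ke), axis=(2, 3))[..., ::dilation, ::dilation]
    b, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (b, ho, wo)


def _conv_raw(x: np.ndarray, w: np.ndarray, pad: tuple[int, int, int, int], dilation: int):
    pt, pb, pl, pr = pad
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    cols, (b, ho, wo) = _im2col(xp, w.shape[2], dilation)
    out = cols @ w.reshape(w.shape[0], -1).T
    return out.reshape(b, ho, wo, w.shape[0]).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           pad: tuple[int, int, int, int] = (0, 0, 0, 0), dilation: int = 1) -> Tensor:
    """Stride-1 2-D correlation.

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin, k, k); ``pad`` is
    (top, bottom, left, right) zero padding applied before the correlation.
    """
    k = w.shape[2]
    out, cols = _conv_raw(x.data, w.data, pad, dilation)
    if b is not None:
        out += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        cout = w.shape[0]
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1).reshape(-1, cout))
        w.accumulate((gmat.T @ cols).reshape(w.shape))
        if b is not None:
            b.accumulate(gmat.sum(axis=0))
        # gradient w.r.t. input: correlate g with the spatially flipped,
        # channel-transposed kernel under the complementary padding
        span = dilation * (k - 1)
        pt, pb, pl, pr = pad
        wf = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        gx, _ = _conv_raw(g, wf, (span - pt, span - pb, span - pl, span - pr), dilation)
        x.accumulate(gx)

    return _node(out, parents, backward)


def zero_insert2d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride-1`` zeros between rows/cols (transposed-conv helper)."""
    b, c, h, w = x.shape
    out = np.zeros((b, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=x.dtype)
    out[:, :, ::stride, ::stride] = x.data

    def backward(g):
        x.accumulate(g[:, :, ::stride, ::stride])

    return _node(out, (x,), backward)


# ---------------------------------------------------------------------------
# pooling / upsampling
# ---------------------------------------------------------------------------

def _pool_view(x: np.ndarray, s: int):
    b, c, h, w = x.shape
    return x.reshape(b, c, h // s, s, w // s, s).transpose(0, 1, 2, 4, 3, 5).reshape(
        b, c, h // s, w // s, s * s)


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    if x.shape[2] % size or x.shape[3] % size:
        raise ValueError(f"spatial dims {x.shape[2:]} not divisible by pool size {size}")
    v = _pool_view(x.data, size)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        b, c, ho, wo = out.shape
        gx = gv.reshape(b, c, ho, wo, size, size).transpose(0, 1, 2, 4, 3, 5).reshape(x.shape)
        x.accumulate(gx)

    return _node(out, (x,), backward)


def avg_pool2d(x: Tensor, size: int = 2) -> Tensor:
    v = _pool_view(x.data, size)
    out = v.mean(axis=-1)

    def backward(g):
        s2 = size * size
        gv = np.broadcast_to(g[..., None] / s2, v.shape)
        b, c, ho, wo = out.shape
        gx = gv.reshape(b, c, ho, wo, size, size).transpose(0, 1, 2, 4, 3, 5).reshape(x.shape)
        x.accumulate(gx)

    return _node(out, (x,), backward)


def nearest_upsample2d(x: Tensor, factor: int = 2) -> Tensor:
    out = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward(g):
        b, c, h, w = x.shape
        gx = g.reshape(b, c, h, factor, w, factor).sum(axis=(3, 5))
        x.accumulate(gx)

    return _node(out, (x,), backward)


# ---------------------------------------------------------------------------
# batch normalization (fused)
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (batch, height, width).

    ``running_mean``/``running_var`` are updated in place when training.
    """
    c = x.shape[1]
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        n = x.data.size // c
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        running_var *= 1.0 - momentum
        running_var += momentum * (v * (n / max(n - 1, 1)))
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
    out = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        beta.accumulate(g.sum(axis=(0, 2, 3)))
        gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        gh = g * gamma.data[None, :, None, None]
        if training:
            n = x.data.size // c
            s1 = gh.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gh * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (gh - s1 / n - xhat * s2 / n) * inv[None, :, None, None]
        else:
            gx = gh * inv[None, :, None, None]
        x.accumulate(gx)

    return _node(out.astype(x.dtype, copy=False), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# fused losses
# ---------------------------------------------------------------------------

def bce_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy between probabilities and a {0,1} target."""
    t = np.asarray(target, dtype=pred.dtype)
    p = np.clip(pred.data, eps, 1.0 - eps)
    val = -(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean()

    def backward(g):
        pred.accumulate(g * (p - t) / (p * (1.0 - p)) / p.size)

    return _node(np.asarray(val, dtype=pred.dtype), (pred,), backward)


def dice_loss(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s)."""
    t = np.asarray(target, dtype=pred.dtype)
    inter = float((pred.data * t).sum())
    denom = float(pred.data.sum() + t.sum()) + smooth
    val = 1.0 - (2.0 * inter + smooth) / denom

    def backward(g):
        gp = -(2.0 * t * denom - (2.0 * inter + smooth)) / (denom * denom)
        pred.accumulate(g * gp)

    return _node(np.asarray(val, dtype=pred.dtype), (pred,), backward)
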