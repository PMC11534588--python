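"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations needed by the super-resolution networks
and losses in this package: 2D convolution (strided, zero-padded),
ReLU/LeakyReLU, pixel shuffle, nearest-neighbour upsampling, 2x2 average
pooling, channel concatenation, elementwise arithmetic, reductions, and a
numerically stable sigmoid binary cross-entropy.  Gradients are accumulated
by a topological-order backward sweep.

All data is float64.  There is no device abstraction and no broadcasting
beyond scalars and the conv bias; shapes must match exactly, which the ops
check eagerly so shape bugs fail loudly at graph-build time.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "add",
    "sub",
    "mul",
    "scale",
    "relu",
    "leaky_relu",
    "conv2d",
    "pixel_shuffle",
    "upsample_nearest2",
    "avg_pool2",
    "concat",
    "reshape",
    "mean",
    "absolute",
    "detach",
    "bce_with_logits_mean",
    "spectral_scale",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward(t.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        if np.isscalar(other):
            return scale(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def item(self) -> float:
        return float(self.data)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _check_same_shape(a: Tensor, b: Tensor, op: str):
    if a.data.shape != b.data.shape:
        raise ValueError(f"{op}: shape mismatch {a.data.shape} vs {b.data.shape}")


# -- elementwise --------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    _check_same_shape(a, b, "add")

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _make(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    _check_same_shape(a, b, "sub")

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(-g)

    return _make(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    _check_same_shape(a, b, "mul")

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * b.data)
        if b.requires_grad:
            b._accumulate(g * a.data)

    return _make(a.data * b.data, (a, b), backward)


def scale(a, s: float) -> Tensor:
    a = _wrap(a)
    s = float(s)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s)

    return _make(a.data * s, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    pos = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * pos)

    return _make(np.where(pos, a.data, 0.0), (a,), backward)


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = _wrap(a)
    pos = a.data > 0
    grad_mask = np.where(pos, 1.0, negative_slope)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * grad_mask)

    return _make(np.where(pos, a.data, a.data * negative_slope), (a,), backward)


def absolute(a) -> Tensor:
    a = _wrap(a)
    sign = np.sign(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * sign)

    return _make(np.abs(a.data), (a,), backward)


def mean(a) -> Tensor:
    a = _wrap(a)
    n = a.data.size

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full(a.data.shape, float(g) / n))

    return _make(np.array(a.data.mean()), (a,), backward)


def detach(a: Tensor) -> Tensor:
    return Tensor(a.data.copy())


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    orig = a.data.shape

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


# -- convolution --------------------------------------------------------

def conv2d(x, weight, bias=None, stride: int = 1, pad: int | None = None) -> Tensor:
    """2D cross-correlation with zero padding; weight (O, C, k, k).

    Computed as a sum over the k*k kernel taps of channel-mixing
    tensordots on shifted views — no im2col materialization, which keeps
    both passes memory-bandwidth friendly at the sizes used here.
    """
    x, weight = _wrap(x), _wrap(weight)
    if bias is not None:
        bias = _wrap(bias)
    if x.data.ndim != 4:
        raise ValueError(f"conv2d: input must be 4D (N,C,H,W), got {x.data.shape}")
    o, c, k, k2 = weight.data.shape
    if k != k2:
        raise ValueError("conv2d: only square kernels supported")
    if x.data.shape[1] != c:
        raise ValueError(
            f"conv2d: expected {c} input channels, got {x.data.shape[1]}"
        )
    if pad is None:
        pad = k // 2
    n, _, h, w = x.data.shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    if pad:
        xp = np.zeros((n, c, hp, wp))
        xp[:, :, pad:-pad, pad:-pad] = x.data
    else:
        xp = x.data
    swv = np.lib.stride_tricks.sliding_window_view
    if stride == 1:
        win = swv(xp, (k, k), axis=(2, 3))  # (N, C, Ho, Wo, k, k), a view
        out = np.einsum("nchwij,ocij->nohw", win, weight.data, optimize=True)
    else:
        win = None
        out = np.zeros((o, n, ho, wo))
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki : ki + stride * ho : stride,
                        kj : kj + stride * wo : stride]
                out += np.tensordot(weight.data[:, :, ki, kj], xs, axes=(1, 1))
        out = np.ascontiguousarray(out.transpose(1, 0, 2, 3))
    if bias is not None:
        out += bias.data[None, :, None, None]

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = weight.requires_grad
        if not (need_x or need_w):
            return
        if stride == 1:
            if need_w:
                weight._accumulate(
                    np.einsum("nohw,nchwij->ocij", g, win, optimize=True))
            if need_x:
                # input gradient = full correlation of g with the flipped kernel
                gp = np.zeros((n, o, h + k - 1, w + k - 1))
                lo = k - 1 - pad
                gp[:, :, lo : lo + ho, lo : lo + wo] = g
                gwin = swv(gp, (k, k), axis=(2, 3))
                x._accumulate(np.einsum(
                    "nohwij,ocij->nchw", gwin,
                    weight.data[:, :, ::-1, ::-1], optimize=True))
            return
        gpad = np.zeros((c, n, hp, wp)) if need_x else None
        gw = np.zeros_like(weight.data) if need_w else None
        for ki in range(k):
            for kj in range(k):
                hs = slice(ki, ki + stride * ho, stride)
                ws = slice(kj, kj + stride * wo, stride)
                if need_w:
                    gw[:, :, ki, kj] = np.tensordot(
                        g, xp[:, :, hs, ws], axes=((0, 2, 3), (0, 2, 3)))
                if need_x:
                    gpad[:, :, hs, ws] += np.tensordot(
                        weight.data[:, :, ki, kj], g, axes=(0, 1))
        if need_w:
            weight._accumulate(gw)
        if need_x:
            gx = gpad.transpose(1, 0, 2, 3)
            x._accumulate(gx[:, :, pad:-pad, pad:-pad] if pad else gx)

    return _make(out, tuple(t for t in (x, weight, bias) if t is not None), backward)


# -- resampling ---------------------------------------------------------

def pixel_shuffle(x, r: int) -> Tensor:
    """Rearrange (N, C*r^2, H, W) -> (N, C, H*r, W*r)."""
    x = _wrap(x)
    n, crr, h, w = x.data.shape
    if crr % (r * r):
        raise ValueError(f"pixel_shuffle: channels {crr} not divisible by {r * r}")
    c = crr // (r * r)
    out = (
        x.data.reshape(n, c, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * r, w * r)
    )

    def backward(g):
        if x.requires_grad:
            gg = (
                g.reshape(n, c, h, r, w, r)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(n, crr, h, w)
            )
            x._accumulate(gg)

    return _make(out, (x,), backward)


def upsample_nearest2(x) -> Tensor:
    x = _wrap(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            gg = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(gg)

    return _make(out, (x,), backward)


def avg_pool2(x) -> Tensor:
    x = _wrap(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2: spatial dims must be even")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gg = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            x._accumulate(gg)

    return _make(out, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return _make(out, tuple(tensors), backward)


# -- losses -------------------------------------------------------------

def bce_with_logits_mean(logits, target) -> Tensor:
    """Mean sigmoid binary cross-entropy; target is a constant array/scalar."""
    logits = _wrap(logits)
    y = np.broadcast_to(np.asarray(target, dtype=np.float64), logits.data.shape)
    x = logits.data
    # -[y log s(x) + (1-y) log(1-s(x))] = (1-y) x + log(1 + e^-x), stable form
    loss = (1.0 - y) * x + np.logaddexp(0.0, -x)
    n = x.size

    def backward(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-x))
            logits._accumulate(float(g) * (sig - y) / n)

    return _make(np.array(loss.mean()), (logits,), backward)


# -- spectral normalization ---------------------------------------------

def spectral_scale(weight, u: np.ndarray, v: np.ndarray, sigma: float) -> Tensor:
    """weight / sigma with the power-iteration vectors treated as constants.

    Gradient: dL/dW = g/sigma - (sum(g * W_bar)/sigma) * outer(u, v) reshaped,
    the exact derivative of W/ (u^T W v) with u, v detached.
    """
    weight = _wrap(weight)
    wbar = weight.data / sigma
    uvt = np.outer(u, v).reshape(weight.data.shape)

    def backward(g):
        if weight.requires_grad:
            coef = float(np.sum(g * wbar)) / sigma
            weight._accumulate(g / sigma - coef * uvt)

    return _make(wbar, (weight,), backward)
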