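"""Differentiable operations for the numpy autodiff engine.

All spatial tensors are NCHW.  Convolutions are stride-1 only: downsampling
in the architectures is done by max-pooling and upsampling by bilinear
interpolation, so stride-1 convs (with padding, dilation and groups) cover
every layer in the networks, including the 2x2 stride-1 transposed
convolution of the micro-codec block (a conv with flipped kernels on a
1-padded input, so it is parameterised directly as Conv2d(k=2, padding=1)).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = [
    "relu", "sigmoid", "add", "concat", "clamp", "conv2d", "batch_norm2d",
    "max_pool2x2", "upsample_bilinear2x", "bce_loss",
]

BCE_EPS = 1e-7


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    requires = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=requires, _parents=parents,
                  _backward=backward if requires else None)


# ---------------------------------------------------------------------------
# pointwise
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = np.maximum(x.data, 0)

    def backward(g):
        return (g * (x.data > 0),)

    return _make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    xd = x.data
    out = np.empty_like(xd)
    pos = xd >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-xd[pos]))
    ex = np.exp(xd[~pos])
    out[~pos] = ex / (1.0 + ex)

    def backward(g):
        return (g * out * (1.0 - out),)

    return _make(out, (x,), backward)


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip to [lo, hi]; gradient flows only through unclipped elements."""
    x = _as_tensor(x)
    out = np.clip(x.data, lo, hi)

    def backward(g):
        return (g * ((x.data > lo) & (x.data < hi)),)

    return _make(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")

    def backward(g):
        return (g, g)

    return _make(a.data + b.data, (a, b), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    if len(tensors) == 1:
        return tensors[0]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding=(0, 0), dilation=(1, 1), groups: int = 1) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), NCHW.

    ``weight`` has shape (C_out, C_in // groups, kh, kw).
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    c_out, c_g, kh, kw = wd.shape
    ph, pw = padding
    dh, dw = dilation
    if c != c_g * groups:
        raise ValueError(
            f"conv2d: input has {c} channels but weight expects {c_g * groups}")

    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else xd
    khe, kwe = dh * (kh - 1) + 1, dw * (kw - 1) + 1
    h_out, w_out = h + 2 * ph - khe + 1, w + 2 * pw - kwe + 1
    if h_out < 1 or w_out < 1:
        raise ValueError(f"conv2d: input {h}x{w} too small for kernel {kh}x{kw} "
                         f"(dilation {dh}x{dw}, padding {ph}x{pw})")

    win = sliding_window_view(xp, (khe, kwe), axis=(2, 3))
    if dh > 1 or dw > 1:
        win = win[..., ::dh, ::dw]
    # win: (n, c, h_out, w_out, kh, kw)

    if groups == 1:
        out = np.tensordot(win, wd, axes=([1, 4, 5], [1, 2, 3]))  # (n,ho,wo,co)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        win_g = w_g = None
    else:
        win_g = win.reshape(n, groups, c_g, h_out, w_out, kh, kw)
        w_g = wd.reshape(groups, c_out // groups, c_g, kh, kw)
        out = np.einsum("ngchwuv,gocuv->ngohw", win_g, w_g, optimize=True)
        out = out.reshape(n, c_out, h_out, w_out)
    if bias is not None:
        out = out + bias.data[:, None, None]

    def backward(g):
        if groups == 1:
            gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
            gwin = np.tensordot(g, wd, axes=([1], [0]))  # (n,ho,wo,c,kh,kw)
            gwin = gwin.transpose(0, 3, 1, 2, 4, 5)
        else:
            gg = g.reshape(n, groups, c_out // groups, h_out, w_out)
            gw = np.einsum("ngohw,ngchwuv->gocuv", gg, win_g,
                           optimize=True).reshape(wd.shape)
            gwin = np.einsum("ngohw,gocuv->ngchwuv", gg, w_g, optimize=True)
            gwin = gwin.reshape(n, c, h_out, w_out, kh, kw)
        gxp = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                gxp[:, :, u * dh:u * dh + h_out, v * dw:v * dw + w_out] += \
                    gwin[:, :, :, :, u, v]
        gx = gxp[:, :, ph:ph + h, pw:pw + w] if (ph or pw) else gxp
        gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
        if bias is not None:
            return gx, gw, gb
        return gx, gw

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, training: bool,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode the batch statistics normalise and the running buffers
    are updated in place (unbiased variance, as is conventional); in eval
    mode the running buffers normalise.
    """
    x = _as_tensor(x)
    xd = x.data
    n, c, h, w = xd.shape
    m = n * h * w
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        unbiased = var * m / (m - 1) if m > 1 else var
        running_var *= (1.0 - momentum)
        running_var += momentum * unbiased
    else:
        mean = running_mean.astype(xd.dtype)
        var = running_var.astype(xd.dtype)

    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[:, None, None]) * ivar[:, None, None]
    out = gamma.data[:, None, None] * xhat + beta.data[:, None, None]

    def backward(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dxhat = g * gamma.data[:, None, None]
        if training:
            s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
            gx = (ivar[:, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        else:
            gx = dxhat * ivar[:, None, None]
        return gx, dgamma, dbeta

    return _make(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2.  Ties route to the first maximum."""
    x = _as_tensor(x)
    xd = x.data
    n, c, h, w = xd.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2: spatial dims {(h, w)} must be even")
    ho, wo = h // 2, w // 2
    xr = xd.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, ho, wo, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gz = np.zeros_like(xr)
        np.put_along_axis(gz, idx[..., None], g[..., None], axis=-1)
        gx = gz.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(n, c, h, w),)

    return _make(out, (x,), backward)


@lru_cache(maxsize=64)
def _interp_matrix(n_in: int, dtype_name: str) -> np.ndarray:
    """Row-interpolation matrix for 2x bilinear upsampling (half-pixel centres)."""
    n_out = 2 * n_in
    src = (np.arange(n_out, dtype=np.float64) + 0.5) / 2.0 - 0.5
    src = np.clip(src, 0.0, n_in - 1)
    i0 = np.floor(src).astype(int)
    frac = src - i0
    i1 = np.minimum(i0 + 1, n_in - 1)
    a = np.zeros((n_out, n_in), dtype=np.dtype(dtype_name))
    rows = np.arange(n_out)
    np.add.at(a, (rows, i0), 1.0 - frac)
    np.add.at(a, (rows, i1), frac)
    return a


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Doubles both spatial dims by bilinear interpolation (a fixed linear map)."""
    x = _as_tensor(x)
    xd = x.data
    ah = _interp_matrix(xd.shape[2], xd.dtype.name)
    aw = _interp_matrix(xd.shape[3], xd.dtype.name)
    t = np.tensordot(xd, aw, axes=([3], [1]))          # (n,c,h,2w)
    out = np.tensordot(t, ah, axes=([2], [1]))         # (n,c,2w,2h)
    out = np.ascontiguousarray(out.transpose(0, 1, 3, 2))

    def backward(g):
        tg = np.tensordot(g, ah, axes=([2], [0]))      # (n,c,2w,h)
        gx = np.tensordot(tg.transpose(0, 1, 3, 2), aw, axes=([3], [0]))
        return (gx,)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(pred: Tensor, target) -> Tensor:
    """Mean binary cross-entropy  -[y log p + (1-y) log(1-p)].

    Predictions are clamped to [1e-7, 1 - 1e-7] before the logs; elements at
    the clamp receive zero gradient.
    """
    pred = _as_tensor(pred)
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    if pred.shape != t.shape:
        raise ValueError(f"bce_loss: shape mismatch {pred.shape} vs {t.shape}")
    t = t.astype(pred.dtype)
    p = np.clip(pred.data, BCE_EPS, 1.0 - BCE_EPS)
    loss = -(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean()

    def backward(g):
        inside = (pred.data > BCE_EPS) & (pred.data < 1.0 - BCE_EPS)
        gp = g * inside * (p - t) / (p * (1.0 - p) * p.size)
        return (gp,)

    return _make(np.asarray(loss, dtype=pred.dtype), (pred,), backward)
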