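"""Convolution, pooling and resampling ops with hand-written backward passes.

All spatial ops assume NCHW layout and stride-1 convolutions; downsampling is
done by explicit pooling, which is how the encoder–decoder backbone uses them.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "max_pool2d", "avg_pool2d", "upsample_nearest2d", "softmax"]


def _im2col(x: np.ndarray, k: int, dilation: int, padding: int) -> np.ndarray:
    """Return patch matrix of shape (N*H*W, C*k*k) for a same-size convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    keff = dilation * (k - 1) + 1
    win = sliding_window_view(xp, (keff, keff), axis=(2, 3))  # N,C,H,W,keff,keff
    win = win[..., ::dilation, ::dilation]                    # N,C,H,W,k,k
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _col2im(cols: np.ndarray, x_shape, k: int, dilation: int,
            padding: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to image layout."""
    n, c, h, w = x_shape
    g = cols.reshape(n, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    xp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i * dilation:i * dilation + h,
               j * dilation:j * dilation + w] += g[:, :, i, j]
    if padding:
        return xp[:, :, padding:-padding, padding:-padding]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           dilation: int = 1) -> Tensor:
    """Stride-1 2D convolution with "same" padding.

    Padding is ``dilation * (k - 1) // 2`` so the output spatial size equals
    the input size for odd kernels regardless of the dilation rate — the
    property that lets dilated stages swap in for plain ones shape-for-shape.
    """
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c or kh != kw:
        raise ValueError(f"incompatible conv shapes {x.shape} / {weight.shape}")
    k = kh
    padding = dilation * (k - 1) // 2
    cols = _im2col(x.data, k, dilation, padding)          # (NHW, Ckk)
    wmat = weight.data.reshape(o, -1)                     # (O, Ckk)
    out = cols @ wmat.T                                   # (NHW, O)
    if bias is not None:
        out = out + bias.data[None, :]
    out = out.reshape(n, h, w, o).transpose(0, 3, 1, 2)

    prev = [p for p in (x, weight, bias) if p is not None]

    def bwd(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * h * w, o)
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=0))
        if weight.requires_grad:
            weight._accum((g2.T @ cols).reshape(weight.shape))
        if x.requires_grad:
            dcols = g2 @ wmat
            x._accum(_col2im(dcols, x.shape, k, dilation, padding))

    return Tensor._make(out, prev, bwd)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial size {h}x{w} not divisible by pool {k}")
    h2, w2 = h // k, w // k
    r = x.data.reshape(n, c, h2, k, w2, k).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h2, w2, k * k)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gr = np.zeros((n, c, h2, w2, k * k), dtype=np.float64)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h2, w2, k, k).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gr.reshape(n, c, h, w))

    return Tensor._make(out, (x,), bwd)


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial size {h}x{w} not divisible by pool {k}")
    h2, w2 = h // k, w // k
    out = x.data.reshape(n, c, h2, k, w2, k).mean(axis=(3, 5))

    def bwd(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gx)

    return Tensor._make(out, (x,), bwd)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    n, c, h, w = x.shape
    out = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)

    def bwd(g):
        x._accum(g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bwd)


def softmax(logits: Tensor, axis: int = 1) -> Tensor:
    """Softmax along `axis`; the max-shift is detached (shift invariance)."""
    shift = logits - Tensor(logits.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)
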