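"""Functional convolution cores used by the layer classes.

Everything operates on NCHW arrays.  The 2-D correlation is implemented with
``sliding_window_view`` + ``einsum`` (im2col); the backward pass scatters the
window gradients back with a small loop over kernel offsets, which is exact
and fast for the kernel sizes used here (at most 4x4).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv2d_forward(x, w, stride, pad):
    """Cross-correlate ``x`` (N,C,H,W) with ``w`` (O,C,kh,kw).

    ``stride`` is (sh, sw); ``pad`` is ((top, bottom), (left, right)).
    Returns (y, cache) where cache is needed by :func:`conv2d_backward`.
    """
    sh, sw = stride
    xp = np.pad(x, ((0, 0), (0, 0), pad[0], pad[1]))
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    y = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
    return y, (xp.shape, win, x.shape, stride, pad, w)


def conv2d_backward(gy, cache):
    """Gradients of :func:`conv2d_forward` w.r.t. input and weights."""
    xp_shape, win, x_shape, (sh, sw), pad, w = cache
    kh, kw = w.shape[2], w.shape[3]
    ho, wo = gy.shape[2], gy.shape[3]
    gw = np.einsum("nchwij,nohw->ocij", win, gy, optimize=True)
    gwin = np.einsum("nohw,ocij->nchwij", gy, w, optimize=True)
    gxp = np.zeros(xp_shape, dtype=gy.dtype)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += gwin[..., i, j]
    (pt, pb), (pl, pr) = pad
    h, wdt = x_shape[2], x_shape[3]
    gx = gxp[:, :, pt : pt + h, pl : pl + wdt]
    return gx, gw


def same_pad(size, kernel, stride):
    """Total 'same' padding so that output = ceil(size / stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return total // 2, total - total // 2


def dilate(x, stride):
    """Insert stride-1 zeros between samples along H and W."""
    sh, sw = stride
    if sh == 1 and sw == 1:
        return x
    n, c, h, w = x.shape
    out = np.zeros((n, c, (h - 1) * sh + 1, (w - 1) * sw + 1), dtype=x.dtype)
    out[:, :, ::sh, ::sw] = x
    return out


def undilate(gx, stride):
    sh, sw = stride
    if sh == 1 and sw == 1:
        return gx
    return gx[:, :, ::sh, ::sw]
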