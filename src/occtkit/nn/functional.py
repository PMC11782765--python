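"""Structured operations (convolution, pooling, softmax) on :class:`Tensor`.

Convolutions are lowered to im2col + matmul; backward passes scatter
gradients with a small loop over kernel offsets so no ``np.add.at`` on
large arrays is needed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _unbroadcast


def _as_padding(padding, kh, kw):
    """Normalize padding to (top, bottom, left, right).

    ``'same'`` follows the TF convention (extra pixel on the bottom/right
    for even kernels), valid for stride 1.
    """
    if padding == "same":
        return ((kh - 1) // 2, kh // 2, (kw - 1) // 2, kw // 2)
    if isinstance(padding, int):
        return (padding,) * 4
    return tuple(padding)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding=0) -> Tensor:
    """2-D cross-correlation. ``x``: (N,C,H,W); ``w``: (Cout,Cin,kh,kw)."""
    N, C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    if Cin != C:
        raise ValueError(f"channel mismatch: input {C}, weight expects {Cin}")
    pt, pb, pl, pr = _as_padding(padding, kh, kw)
    if pt or pb or pl or pr:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    else:
        xp = x.data
    Hp, Wp = xp.shape[2:]
    if kh > Hp or kw > Wp:
        raise ValueError(f"kernel {kh}x{kw} larger than padded input {Hp}x{Wp}")
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(Cout, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out_data = out.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)

    def bw(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, Cout)
        w._accumulate((gmat.T @ cols).reshape(w.shape))
        if b is not None:
            b._accumulate(gmat.sum(axis=0))
        dcols = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw)
        dxp = np.zeros(xp.shape, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        x._accumulate(dxp[:, :, pt:Hp - pb, pl:Wp - pr])

    parents = (x, w) if b is None else (x, w, b)
    return x._make(out_data, parents, bw)


def dilate2d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride - 1`` zeros between spatial samples (for transposed conv)."""
    if stride == 1:
        return x
    N, C, H, W = x.shape
    out_data = np.zeros((N, C, (H - 1) * stride + 1, (W - 1) * stride + 1),
                        dtype=np.float32)
    out_data[:, :, ::stride, ::stride] = x.data

    def bw(g):
        x._accumulate(g[:, :, ::stride, ::stride])

    return x._make(out_data, (x,), bw)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed convolution, parameterized directly by its equivalent
    forward-convolution weight (Cout, Cin, k, k) applied to the zero-dilated
    input. Output size: (H-1)*stride + k - 2*padding."""
    k = w.shape[2]
    return conv2d(dilate2d(x, stride), w, b, stride=1, padding=k - 1 - padding)


def _pool_windows(xp: np.ndarray, k: int, stride: int):
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    return win.reshape(win.shape[:4] + (k * k,))


def _pool_offsets(H, W, Ho, Wo, k, stride, padding):
    """Per kernel-offset slices avoiding any padded copy of the input.

    Yields (i, j, out row/col slices, input row/col slices) such that the
    input slice is the window element (i, j) for every valid output cell.
    """
    for i in range(k):
        oh0 = max(0, -(-(padding - i) // stride))
        oh1 = min(Ho - 1, (H - 1 - i + padding) // stride)
        if oh1 < oh0:
            continue
        for j in range(k):
            ow0 = max(0, -(-(padding - j) // stride))
            ow1 = min(Wo - 1, (W - 1 - j + padding) // stride)
            if ow1 < ow0:
                continue
            rs = slice(oh0 * stride + i - padding,
                       oh1 * stride + i - padding + 1, stride)
            cs = slice(ow0 * stride + j - padding,
                       ow1 * stride + j - padding + 1, stride)
            yield (i, j, slice(oh0, oh1 + 1), slice(ow0, ow1 + 1), rs, cs)


def max_pool2d(x: Tensor, k: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    N, C, H, W = x.shape
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    out_data = np.full((N, C, Ho, Wo), -np.inf, dtype=np.float32)
    idx = np.zeros((N, C, Ho, Wo), dtype=np.int8)
    offsets = list(_pool_offsets(H, W, Ho, Wo, k, stride, padding))
    for i, j, ohs, ows, rs, cs in offsets:
        cand = x.data[:, :, rs, cs]
        region = out_data[:, :, ohs, ows]
        sel = cand > region
        np.copyto(region, cand, where=sel)
        np.copyto(idx[:, :, ohs, ows], np.int8(i * k + j), where=sel)

    def bw(g):
        dx = np.zeros(x.shape, dtype=np.float32)
        for i, j, ohs, ows, rs, cs in offsets:
            dx[:, :, rs, cs] += g[:, :, ohs, ows] * (idx[:, :, ohs, ows] == i * k + j)
        x._accumulate(dx)

    return x._make(out_data, (x,), bw)


def avg_pool2d(x: Tensor, k: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Average pooling, excluding padded cells from the divisor."""
    N, C, H, W = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    ones = np.pad(np.ones((1, 1, H, W), dtype=np.float32),
                  ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    counts = _pool_windows(ones, k, stride).sum(axis=-1)
    win = _pool_windows(xp, k, stride)
    out_data = win.sum(axis=-1) / counts
    Ho, Wo = out_data.shape[2:]
    Hp, Wp = xp.shape[2:]

    def bw(g):
        gc = g / counts
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += gc
        x._accumulate(dxp[:, :, padding:Hp - padding, padding:Wp - padding])

    return x._make(out_data, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    return x.elu(alpha)


def softplus(x: Tensor) -> Tensor:
    # log(1 + e^x) = max(x,0) + log1p(e^{-|x|}), built from stable pieces
    pos = x.relu()
    return pos + ((-x.abs()).exp() + 1.0).log()


def softsign(x: Tensor) -> Tensor:
    return x / (x.abs() + 1.0)


def gelu(x: Tensor) -> Tensor:
    return x * 0.5 * ((x * np.float32(1.0 / np.sqrt(2.0))).erf() + 1.0)


ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "elu": elu,
    "tanh": lambda t: t.tanh(),
    "softplus": softplus,
    "softsign": softsign,
    "leaky_relu": lambda t: t.leaky_relu(0.2),
    "gelu": gelu,
    "sigmoid": sigmoid,
}
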