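"""Differentiable signal-processing primitives (convolution, pooling, softmax).

Convolutions are implemented with strided window views feeding a single
``tensordot`` so the heavy lifting stays inside BLAS; backward passes
are analytic and are checked against finite differences in the tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = [
    "conv1d",
    "avg_pool1d",
    "spatial_collapse",
    "softmax",
    "log_softmax",
    "dropout",
]


def conv1d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    dilation: int = 1,
    pad_left: int = 0,
    pad_right: int = 0,
) -> Tensor:
    """Cross-correlation along the last axis.

    x: [B, C_in, T], w: [C_out, C_in, K].  Output length is
    ``T + pad_left + pad_right - (K-1)*dilation`` (stride 1).
    """
    if dilation < 1:
        raise ValueError(f"dilation must be >= 1, got {dilation}")
    B, C_in, T = x.data.shape
    C_out, C_in_w, K = w.data.shape
    if C_in != C_in_w:
        raise ValueError(f"conv1d channel mismatch: input has {C_in}, kernel expects {C_in_w}")
    span = (K - 1) * dilation + 1
    T_out = T + pad_left + pad_right - span + 1
    if T_out < 1:
        raise ValueError(
            f"conv1d input too short: T={T} with padding ({pad_left},{pad_right}) "
            f"cannot fit kernel span {span}"
        )
    if pad_left or pad_right:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad_left, pad_right)))
    else:
        xp = x.data
    # [B, C_in, T_out, K] view: window t picks taps t, t+d, ..., t+(K-1)d
    win = sliding_window_view(xp, span, axis=2)[:, :, :T_out, ::dilation]
    out_data = np.tensordot(win, w.data, axes=([1, 3], [1, 2]))  # [B, T_out, C_out]
    out_data = np.ascontiguousarray(out_data.transpose(0, 2, 1))
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):  # g: [B, C_out, T_out]
        if w.requires_grad:
            # [C_out, C_in, K]
            gw = np.tensordot(g, win, axes=([0, 2], [0, 2]))
            w._accum(gw)
        if x.requires_grad:
            gx_pad = np.zeros_like(xp)
            for k in range(K):
                lo = k * dilation
                # w[:, :, k]^T @ g  -> [B, C_in, T_out]
                gx_pad[:, :, lo : lo + T_out] += np.einsum(
                    "oc,bot->bct", w.data[:, :, k], g, optimize=True
                )
            if pad_left or pad_right:
                gx = gx_pad[:, :, pad_left : pad_left + T]
            else:
                gx = gx_pad
            x._accum(gx)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))

    return Tensor._make(out_data, parents, backward)


def avg_pool1d(x: Tensor, length: int, stride: int | None = None) -> Tensor:
    """Average pooling along the last axis of [..., T]."""
    if length < 1:
        raise ValueError("pool length must be >= 1")
    stride = length if stride is None else stride
    if stride < 1:
        raise ValueError("pool stride must be >= 1")
    T = x.data.shape[-1]
    T_out = (T - length) // stride + 1
    if T_out < 1:
        raise ValueError(f"avg_pool1d input too short: T={T} < pool length {length}")
    win = sliding_window_view(x.data, length, axis=-1)[..., ::stride, :][..., :T_out, :]
    out_data = win.mean(axis=-1)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        scale = 1.0 / length
        # within one offset j the written positions j + stride*t are distinct,
        # so plain slice accumulation is collision-free
        for j in range(length):
            gx[..., j : j + stride * T_out : stride] += g * scale
        x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


def spatial_collapse(x: Tensor, w: Tensor) -> Tensor:
    """Depthwise collapse of the spatial-channel axis.

    x: [B, F, C, T], w: [F, M, C] -> out [B, F*M, T] where
    out[b, f*M+m, t] = sum_c w[f, m, c] * x[b, f, c, t].
    """
    B, F, C, T = x.data.shape
    Fw, M, Cw = w.data.shape
    if (F, C) != (Fw, Cw):
        raise ValueError(
            f"spatial_collapse mismatch: input [F={F}, C={C}] vs weights [F={Fw}, C={Cw}]"
        )
    out_data = np.einsum("bfct,fmc->bfmt", x.data, w.data, optimize=True)
    out_data = out_data.reshape(B, F * M, T)

    def backward(g):
        g4 = g.reshape(B, F, M, T)
        if x.requires_grad:
            x._accum(np.einsum("bfmt,fmc->bfct", g4, w.data, optimize=True))
        if w.requires_grad:
            w._accum(np.einsum("bfmt,bfct->fmc", g4, x.data, optimize=True))

    return Tensor._make(out_data, (x, w), backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple, eps: float):
    """Fused training-mode batch normalization over ``axes``.

    gamma/beta are broadcast-shaped.  Returns (out, batch_mean,
    batch_var) with the analytic backward pass; the statistics are
    plain arrays for the running-average update.
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv_sd = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv_sd
    out_data = gamma.data * xhat + beta.data
    n = int(np.prod([x.data.shape[a] for a in axes]))

    def backward(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes, keepdims=True).reshape(beta.data.shape))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes, keepdims=True).reshape(gamma.data.shape))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.sum(axis=axes, keepdims=True) / n
            m2 = (dxhat * xhat).sum(axis=axes, keepdims=True) / n
            x._accum(inv_sd * (dxhat - m1 - xhat * m2))

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out, mu.reshape(-1), var.reshape(-1)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    if not 0.0 <= p < 1.0:
        raise ValueError(f"dropout probability must be in [0, 1), got {p}")
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(mask)
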