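"""Temporal decoder (dilated-causal residual stack) and multi-head attention.

The decoder is a TCN variant: ``n_blocks`` residual blocks, each with
``layers_per_block`` dilated causal convolutions (all layers in block j
share dilation ``dilation_base**(j-1)``), batch-norm + ELU + dropout
after every convolution, and an additional ELU after each residual sum.
Its receptive field is 1 + m*(K-1)*(b^n - 1)/(b - 1).

The attention unit is standard scaled dot-product multi-head
self-attention over the time axis with per-head projection matrices and
an output projection, no positional encoding (the decoder supplies the
temporal structure) and no feed-forward sublayer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm,
    Conv1d,
    Dropout,
    Module,
    Parameter,
    Tensor,
    concat,
    glorot_uniform,
    no_grad,
)
from .nn.functional import softmax

__all__ = [
    "TemporalDecoderConfig",
    "dilated_causal_conv",
    "receptive_field",
    "empirical_receptive_field",
    "TemporalDecoder",
    "MultiHeadAttention",
    "ATT",
]


@dataclass
class TemporalDecoderConfig:
    n_blocks: int = 2
    layers_per_block: int = 2
    kernel_length: int = 4
    dilation_base: int = 2
    n_filters: int = 16
    dropout_p: float = 0.3

    def __post_init__(self):
        if self.n_blocks < 1 or self.layers_per_block < 1 or self.kernel_length < 1:
            raise ValueError("n_blocks, layers_per_block and kernel_length must be >= 1")
        if self.dilation_base < 2:
            raise ValueError(f"dilation_base must be >= 2, got {self.dilation_base}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError(f"dropout_p must be in [0, 1), got {self.dropout_p}")

    def dilation(self, block_index: int) -> int:
        """Dilation shared by every layer of block ``block_index`` (0-based)."""
        return self.dilation_base ** block_index


def dilated_causal_conv(x: np.ndarray, f: np.ndarray, d: int) -> np.ndarray:
    """Reference dilated causal convolution on a 1-D sequence.

    out[t] = sum_i f[i] * x[t - d*i], with x[j] = 0 for j < 0, so the
    output has the same length as the input and out[t] depends only on
    x[0..t].
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    if x.ndim != 1 or f.ndim != 1:
        raise ValueError("x and f must be 1-D sequences")
    k = f.size
    if k < 1:
        raise ValueError("kernel must have at least one tap")
    if d < 1:
        raise ValueError(f"dilation must be >= 1, got {d}")
    n = x.size
    out = np.zeros(n)
    for i in range(k):
        shift = d * i
        if shift < n:
            out[shift:] += f[i] * x[: n - shift]
    return out


def receptive_field(cfg: TemporalDecoderConfig) -> int:
    """r = 1 + m*(K-1)*(b^n - 1)/(b - 1)."""
    m, K, b, n = cfg.layers_per_block, cfg.kernel_length, cfg.dilation_base, cfg.n_blocks
    return 1 + m * (K - 1) * (b**n - 1) // (b - 1)


class _ResidualBlock(Module):
    def __init__(self, cfg: TemporalDecoderConfig, dilation: int, rng):
        super().__init__()
        d = cfg.n_filters
        self.convs = [
            Conv1d(d, d, cfg.kernel_length, dilation=dilation, padding="causal", bias=False, rng=rng)
            for _ in range(cfg.layers_per_block)
        ]
        self.bns = [BatchNorm(d) for _ in range(cfg.layers_per_block)]
        self.drops = [
            Dropout(cfg.dropout_p, rng=np.random.default_rng(rng.integers(2**31)))
            for _ in range(cfg.layers_per_block)
        ]

    def forward(self, x, linear: bool = False):
        h = x
        for conv, bn, drop in zip(self.convs, self.bns, self.drops):
            h = conv(h)
            if not linear:
                h = drop(bn(h).elu())
        out = h + x  # feature counts always match: identity residual
        return out if linear else out.elu()


class TemporalDecoder(Module):
    """Causal feature decoder, [B, d, N] -> [B, d, N]."""

    def __init__(self, cfg: TemporalDecoderConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.blocks = [_ResidualBlock(cfg, cfg.dilation(j), rng) for j in range(cfg.n_blocks)]

    def forward(self, x, linear: bool = False):
        if x.data.shape[1] != self.cfg.n_filters:
            raise ValueError(
                f"expected {self.cfg.n_filters} features on axis 1, got {x.data.shape[1]}"
            )
        for block in self.blocks:
            x = block(x, linear=linear)
        return x


def empirical_receptive_field(decoder: TemporalDecoder, t: int) -> int:
    """Temporal extent of the input that influences decoder output at time t.

    Probes a linearized copy of the decoder whose weights are replaced
    by their absolute values (plus a small floor), so contributions
    cannot cancel: an input position influences ``t`` iff an impulse
    there produces a nonzero response at ``t``.  Returns the span from
    the earliest influencing position to ``t`` inclusive — the quantity
    the closed-form receptive-field expression describes — so it equals
    min(receptive_field(cfg), t+1).  (For a few dilation stacks, e.g.
    a single kernel-2 layer per block with base-3 dilation, the span
    contains interior positions with no influence; the span, not the
    influence count, is what grows as 1 + m(K-1)(b^n-1)/(b-1).)
    """
    if t < 0:
        raise ValueError(f"time index must be non-negative, got {t}")
    probe = TemporalDecoder(decoder.cfg, rng=np.random.default_rng(0))
    state = {k: np.abs(v) + 1e-3 for k, v in decoder.state_dict().items()}
    probe.load_state_dict(state)
    probe.eval()
    d = decoder.cfg.n_filters
    N = t + 1
    earliest = t
    with no_grad():
        for s in range(N):
            x = np.zeros((1, d, N), dtype=np.float32)
            x[0, :, s] = 1.0
            out = probe(Tensor(x), linear=True)
            if np.any(np.abs(out.data[0, :, t]) > 0):
                earliest = s
                break
    return t - earliest + 1


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with H heads over [*, N, d].

    Per head h: Q_h = X W_h^Q, K_h = X W_h^K, V_h = X W_h^V with
    projection matrices of shape [d, d/H]; attention weights are
    row-softmax(Q_h K_h^T / sqrt(d_k)); head outputs are concatenated
    and mapped back to d by W_o of shape [H*d_v, d].
    """

    def __init__(self, d: int, n_heads: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        if d % n_heads != 0:
            raise ValueError(f"model dimension {d} not divisible by {n_heads} heads")
        rng = rng or np.random.default_rng()
        self.d = d
        self.n_heads = n_heads
        self.d_k = d // n_heads
        self.d_v = d // n_heads
        self.W_Q = [Parameter(glorot_uniform(rng, (d, self.d_k), d, self.d_k)) for _ in range(n_heads)]
        self.W_K = [Parameter(glorot_uniform(rng, (d, self.d_k), d, self.d_k)) for _ in range(n_heads)]
        self.W_V = [Parameter(glorot_uniform(rng, (d, self.d_v), d, self.d_v)) for _ in range(n_heads)]
        self.W_O = Parameter(glorot_uniform(rng, (n_heads * self.d_v, d), n_heads * self.d_v, d))

    def attention_weights(self, X) -> list[np.ndarray]:
        """Row-stochastic attention matrices A_h, for inspection/tests."""
        X = X if isinstance(X, Tensor) else Tensor(np.asarray(X))
        with no_grad():
            return [a.data for a in self._scores(X)]

    def _scores(self, X: Tensor) -> list[Tensor]:
        scale = 1.0 / np.sqrt(self.d_k)
        out = []
        for h in range(self.n_heads):
            Q = X @ self.W_Q[h]
            K = X @ self.W_K[h]
            out.append(softmax((Q @ K.transpose(*_swap_last(X.ndim))) * scale, axis=-1))
        return out

    def forward(self, X):
        squeeze = False
        if isinstance(X, np.ndarray):
            X = Tensor(X)
        if X.ndim == 2:
            X = X.reshape(1, *X.shape)
            squeeze = True
        heads = []
        scale = 1.0 / np.sqrt(self.d_k)
        for h in range(self.n_heads):
            Q = X @ self.W_Q[h]
            K = X @ self.W_K[h]
            V = X @ self.W_V[h]
            A = softmax((Q @ K.transpose(0, 2, 1)) * scale, axis=-1)
            heads.append(A @ V)
        out = concat(heads, axis=-1) @ self.W_O
        return out.reshape(*out.shape[1:]) if squeeze else out


def _swap_last(ndim):
    axes = list(range(ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return axes


def multi_head_attention(X, params: MultiHeadAttention):
    """Functional form of the attention unit (see MultiHeadAttention)."""
    return params(X)


class ATT(Module):
    """Temporal decoder followed by the attention unit, [B, d, N] -> [B, d, N]."""

    def __init__(
        self,
        decoder: TemporalDecoder | None,
        attention: MultiHeadAttention | None,
        attn_residual: bool = False,
    ):
        super().__init__()
        self.decoder = decoder
        self.attention = attention
        self.attn_residual = attn_residual

    def forward(self, x):
        h = self.decoder(x) if self.decoder is not None else x
        if self.attention is None:
            return h
        a = self.attention(h.transpose(0, 2, 1)).transpose(0, 2, 1)
        return a + h if self.attn_residual else a
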