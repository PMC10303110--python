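"""Multi-scale feature extraction block.

Parallel temporal-convolution branches with different kernel lengths act
as frequency filters (long kernels pick up low frequencies, short ones
high frequencies); a depthwise convolution spanning the full channel
axis collapses the spatial dimension; branch outputs are fused by
concatenation and refined by a further convolution.  Layer inventory
and defaults: 16 temporal filters per branch (kernels 64 and 16),
depthwise over all 22 channels, average pooling 8 then 7, dropout 0.3,
fusion convolution of 16 filters with kernel 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    AvgPool1d,
    BatchNorm,
    Conv1d,
    Dropout,
    Module,
    SpatialCollapse,
    concat,
)

__all__ = ["MSFEConfig", "MSFE", "elu", "count_parameters", "parameter_breakdown"]


def elu(x):
    """ELU(x) = e^x - 1 for x < 0, x for x >= 0.  Works on scalars and arrays."""
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, np.expm1(x), x)
    return out.item() if out.ndim == 0 else out


@dataclass
class MSFEConfig:
    branch_kernel_lengths: list[int] = field(default_factory=lambda: [64, 16])
    n_temporal_filters: int = 16
    depth_multiplier: int = 1
    spatial_kernel_channels: int = 22
    pool1_length: int = 8
    fusion_filters: int = 16
    fusion_kernel_length: int = 16
    pool2_length: int = 7
    dropout_p: float = 0.3
    # None -> stride equals the pool length (non-overlapping pooling);
    # an integer exposes the literal stride-1 reading
    pool_stride1: int | None = None
    pool_stride2: int | None = None
    # whether the post-pool convolution lives inside each branch (the
    # alternative reading of the layer table) or after fusion (default)
    conv2_per_branch: bool = False

    def __post_init__(self):
        if len(self.branch_kernel_lengths) < 1:
            raise ValueError("need at least one branch")
        for k in self.branch_kernel_lengths:
            if k < 1:
                raise ValueError(f"kernel lengths must be >= 1, got {k}")
        for name in ("n_temporal_filters", "depth_multiplier", "spatial_kernel_channels",
                     "pool1_length", "fusion_filters", "fusion_kernel_length", "pool2_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError(f"dropout_p must be in [0, 1), got {self.dropout_p}")

    @property
    def n_branches(self) -> int:
        return len(self.branch_kernel_lengths)

    @property
    def out_features(self) -> int:
        if self.conv2_per_branch:
            return self.n_branches * self.fusion_filters
        return self.fusion_filters

    def _pool_out(self, T: int, length: int, stride: int | None) -> int:
        stride = length if stride is None else stride
        return (T - length) // stride + 1

    def out_time(self, T: int) -> int:
        t1 = self._pool_out(T, self.pool1_length, self.pool_stride1)
        if t1 < 1:
            raise ValueError(f"T={T} too short for pooling stage 1 (length {self.pool1_length})")
        t2 = self._pool_out(t1, self.pool2_length, self.pool_stride2)
        if t2 < 1:
            raise ValueError(
                f"T={T} too short: {t1} samples after pooling stage 1 cannot feed "
                f"pooling stage 2 (length {self.pool2_length})"
            )
        return t2

    def min_time(self) -> int:
        s1 = self.pool1_length if self.pool_stride1 is None else self.pool_stride1
        return self.pool1_length + s1 * (self.pool2_length - 1)


class _ConvBlock(Module):
    """Feature conv -> BN -> ELU -> pool -> dropout tail."""

    def __init__(self, in_features, cfg: MSFEConfig, rng):
        super().__init__()
        self.conv = Conv1d(
            in_features, cfg.fusion_filters, cfg.fusion_kernel_length,
            padding="same", bias=False, rng=rng,
        )
        self.bn = BatchNorm(cfg.fusion_filters)
        self.pool = AvgPool1d(cfg.pool2_length, cfg.pool_stride2)
        self.drop = Dropout(cfg.dropout_p, rng=np.random.default_rng(rng.integers(2**31)))

    def forward(self, x):
        return self.drop(self.pool(self.bn(self.conv(x)).elu()))


class _Branch(Module):
    def __init__(self, kernel_length: int, cfg: MSFEConfig, rng):
        super().__init__()
        F, C, M = cfg.n_temporal_filters, cfg.spatial_kernel_channels, cfg.depth_multiplier
        self.temporal = Conv1d(1, F, kernel_length, padding="same", bias=False, rng=rng)
        self.bn1 = BatchNorm(F)
        self.spatial = SpatialCollapse(F, C, M, rng=rng)
        self.bn2 = BatchNorm(F * M)
        self.pool = AvgPool1d(cfg.pool1_length, cfg.pool_stride1)
        self.drop = Dropout(cfg.dropout_p, rng=np.random.default_rng(rng.integers(2**31)))
        self.conv2 = _ConvBlock(F * M, cfg, rng) if cfg.conv2_per_branch else None

    def forward(self, x4):
        # x4: [B, F, C, T] after the shared temporal-conv reshape in MSFE
        h = self.spatial(x4)  # [B, F*M, T]
        h = self.bn2(h).elu()
        h = self.drop(self.pool(h))
        if self.conv2 is not None:
            h = self.conv2(h)
        return h


class MSFE(Module):
    """[B, C, T] -> [B, out_features, out_time(T)]."""

    def __init__(self, cfg: MSFEConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.branches = [_Branch(k, cfg, rng) for k in cfg.branch_kernel_lengths]
        if cfg.conv2_per_branch:
            self.fusion = None
        else:
            in_features = cfg.n_branches * cfg.n_temporal_filters * cfg.depth_multiplier
            self.fusion = _ConvBlock(in_features, cfg, rng)

    def forward(self, x):
        B, C, T = x.data.shape
        if C != self.cfg.spatial_kernel_channels:
            raise ValueError(
                f"expected {self.cfg.spatial_kernel_channels} channels, got {C}"
            )
        if T < self.cfg.min_time():
            raise ValueError(
                f"T={T} too short for the pooling cascade; minimum is {self.cfg.min_time()}"
            )
        outs = []
        for br in self.branches:
            # temporal conv treats each channel independently: fold C into batch
            h = br.temporal(x.reshape(B * C, 1, T))  # [B*C, F, T]
            # normalizing per temporal filter over (batch, channel, time) is
            # identical on the folded layout and keeps the data contiguous
            h = br.bn1(h)
            Fn = h.data.shape[1]
            h = h.reshape(B, C, Fn, T).transpose(0, 2, 1, 3)  # [B, F, C, T]
            outs.append(br(h))
        fused = outs[0] if len(outs) == 1 else concat(outs, axis=1)
        if self.fusion is not None:
            fused = self.fusion(fused)
        return fused


def count_parameters(block: Module) -> int:
    """Number of trainable scalar parameters in a model component."""
    return int(sum(p.data.size for p in block.parameters() if getattr(p, "trainable", True)))


def parameter_breakdown(block: Module) -> dict[str, int]:
    """Per-parameter counts; values sum exactly to count_parameters(block)."""
    return {
        name: int(p.data.size)
        for name, p in block.named_parameters()
        if getattr(p, "trainable", True)
    }
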