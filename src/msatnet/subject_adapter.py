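"""Bottleneck subject adapter and the freeze/fine-tune machinery.

The adapter is a residual bottleneck: features are down-projected,
passed through ELU, up-projected back to the original dimension, and
added to the input.  With a zero-initialized up-projection the adapter
is exactly the identity at insertion, so augmenting a pre-trained model
does not change its outputs until fine-tuning starts.  During subject
transfer only adapter parameters are trainable; everything else is
frozen bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor

__all__ = [
    "AdapterConfig",
    "Adapter",
    "insert_adapters",
    "freeze_all_but_adapters",
    "adapter_parameter_fraction",
]


@dataclass
class AdapterConfig:
    input_dim: int
    bottleneck_dim: int | None = None  # default d // 4
    zero_init_up: bool = True

    def __post_init__(self):
        if self.bottleneck_dim is None:
            self.bottleneck_dim = max(1, self.input_dim // 4)
        if not 1 <= self.bottleneck_dim < self.input_dim:
            raise ValueError(
                f"bottleneck_dim must satisfy 1 <= r_b < d={self.input_dim}, "
                f"got {self.bottleneck_dim}"
            )


class Adapter(Module):
    """x -> x + U @ ELU(D @ x + b_D) + b_U on the last (feature) axis."""

    def __init__(self, cfg: AdapterConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        self.down = Linear(cfg.input_dim, cfg.bottleneck_dim, rng=rng)
        self.up = Linear(cfg.bottleneck_dim, cfg.input_dim, rng=rng, zero_init=cfg.zero_init_up)

    def forward(self, x):
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        if x.data.shape[-1] != self.cfg.input_dim:
            raise ValueError(
                f"adapter expects feature dim {self.cfg.input_dim}, got {x.data.shape[-1]}"
            )
        return x + self.up(self.down(x).elu())


def insert_adapters(model, cfg: AdapterConfig | None = None, seed: int = 0):
    """Attach an adapter at the model's configured site (after the
    temporal-attention stage, before the classification head).

    With ``zero_init_up`` the augmented model computes exactly the same
    function as the original.  Returns the model for chaining.
    """
    if getattr(model, "adapter", None) is not None:
        raise ValueError("model already contains adapters")
    if cfg is None:
        cfg = AdapterConfig(input_dim=model.feature_dim)
    elif cfg.input_dim != model.feature_dim:
        raise ValueError(
            f"adapter input_dim {cfg.input_dim} != model feature dim {model.feature_dim}"
        )
    model.adapter = Adapter(cfg, rng=np.random.default_rng(seed))
    model.adapter.train(model.training)
    return model


def freeze_all_but_adapters(model, train_head: bool = False):
    """Mark only adapter parameters trainable (optionally the head too).

    A subsequent optimizer step leaves every non-adapter parameter
    bit-identical; see the Adam implementation, which skips frozen
    parameters entirely.
    """
    if getattr(model, "adapter", None) is None:
        raise ValueError("insert_adapters must be called before freezing")
    for name, p in model.named_parameters():
        if name.startswith("adapter."):
            p.trainable = True
        elif train_head and name.startswith("head."):
            p.trainable = True
        else:
            p.trainable = False
    return model


def adapter_parameter_fraction(model) -> float:
    """Trainable adapter parameters as a fraction of all model parameters."""
    total = sum(p.data.size for _, p in model.named_parameters())
    adapter = sum(p.data.size for n, p in model.named_parameters() if n.startswith("adapter."))
    return adapter / total
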