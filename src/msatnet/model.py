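"""End-to-end classifier: MSFE -> ATT -> (optional adapter) -> dense softmax."""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .data_io import EpochSet
from .msfe import MSFE, MSFEConfig, count_parameters, parameter_breakdown
from .nn import Module, Tensor, no_grad
from .nn.functional import softmax
from .nn.optim import max_norm_rescale
from .subject_adapter import Adapter, AdapterConfig
from .temporal_transformer import (
    ATT,
    MultiHeadAttention,
    TemporalDecoder,
    TemporalDecoderConfig,
)

__all__ = [
    "MSATConfig",
    "MSATModel",
    "build_model",
    "predict",
    "apply_max_norm",
    "save_model",
    "load_model",
    "ABLATION_MODES",
]

ABLATION_MODES = ("full", "msfe_only", "msfe+decoder", "msfe+attention")


@dataclass
class MSATConfig:
    """Complete hyperparameter record for one model build."""

    msfe: MSFEConfig = field(default_factory=MSFEConfig)
    decoder: TemporalDecoderConfig = field(default_factory=TemporalDecoderConfig)
    n_heads: int = 2
    adapter: AdapterConfig | None = None
    n_classes: int = 4
    max_norm_dense: float = 0.25
    ablation: str = "full"
    attn_residual: bool = False

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError(f"need at least 2 classes, got {self.n_classes}")
        if self.max_norm_dense <= 0:
            raise ValueError("max_norm_dense must be positive")
        if self.ablation not in ABLATION_MODES:
            raise ValueError(f"ablation must be one of {ABLATION_MODES}, got {self.ablation!r}")


class MSATModel(Module):
    """Maps [B, C, T] trials to class probabilities."""

    def __init__(self, cfg: MSATConfig, C: int, T: int, rng: np.random.Generator):
        super().__init__()
        from .nn import Linear

        if C != cfg.msfe.spatial_kernel_channels:
            cfg = dataclasses.replace(
                cfg, msfe=dataclasses.replace(cfg.msfe, spatial_kernel_channels=C)
            )
        self.cfg = cfg
        self.n_channels = C
        self.n_samples = T
        self.msfe = MSFE(cfg.msfe, rng=rng)
        self.feature_dim = cfg.msfe.out_features
        self.seq_len = cfg.msfe.out_time(T)

        dec = attn = None
        if cfg.ablation in ("full", "msfe+decoder"):
            dcfg = dataclasses.replace(cfg.decoder, n_filters=self.feature_dim)
            dec = TemporalDecoder(dcfg, rng=rng)
        if cfg.ablation in ("full", "msfe+attention"):
            attn = MultiHeadAttention(self.feature_dim, cfg.n_heads, rng=rng)
        self.att = ATT(dec, attn, attn_residual=cfg.attn_residual)
        self.adapter: Adapter | None = None
        if cfg.adapter is not None:
            acfg = dataclasses.replace(cfg.adapter, input_dim=self.feature_dim)
            self.adapter = Adapter(acfg, rng=rng)
        self.head = Linear(self.feature_dim * self.seq_len, cfg.n_classes, rng=rng)

    def forward(self, x) -> Tensor:
        """Returns logits [B, n_classes]."""
        if isinstance(x, np.ndarray):
            x = Tensor(x.astype(np.float32, copy=False))
        B = x.data.shape[0]
        if x.data.shape[1] != self.n_channels:
            raise ValueError(
                f"model built for {self.n_channels} channels, got {x.data.shape[1]}"
            )
        h = self.msfe(x)  # [B, F, N]
        h = self.att(h)
        if self.adapter is not None:
            h = self.adapter(h.transpose(0, 2, 1)).transpose(0, 2, 1)
        flat = h.reshape(B, self.feature_dim * self.seq_len)
        return self.head(flat)

    def predict_proba(self, x) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                probs = softmax(self.forward(x), axis=-1).data
        finally:
            self.train(was_training)
        return probs

    def parameter_audit(self) -> dict[str, int]:
        """Trainable-parameter counts per top-level component plus total."""
        audit: dict[str, int] = {}
        for comp in ("msfe", "att", "adapter", "head"):
            mod = getattr(self, comp, None)
            audit[comp] = count_parameters(mod) if isinstance(mod, Module) else 0
        audit["total"] = sum(audit.values())
        return audit

    def parameter_breakdown(self) -> dict[str, int]:
        return parameter_breakdown(self)


def build_model(cfg: MSATConfig, C: int, T: int, seed: int = 0) -> MSATModel:
    """Construct a seeded, Glorot-initialized model and validate shapes."""
    try:
        cfg.msfe.out_time(T)
    except ValueError as e:
        raise ValueError(f"MSFE stage rejects input length: {e}") from e
    return MSATModel(cfg, C, T, rng=np.random.default_rng(seed))


def predict(model: MSATModel, es: EpochSet, batch_size: int = 64):
    """(labels, probabilities) for every trial; argmax ties break low."""
    if es.n_channels != model.n_channels or es.n_samples != model.n_samples:
        raise ValueError(
            f"data shape [C={es.n_channels}, T={es.n_samples}] does not match model "
            f"[C={model.n_channels}, T={model.n_samples}]"
        )
    probs = np.concatenate(
        [
            model.predict_proba(es.data[i : i + batch_size])
            for i in range(0, es.n_trials, batch_size)
        ]
    )
    return probs.argmax(axis=1), probs


def apply_max_norm(model: MSATModel, c: float | None = None) -> None:
    """Rescale each output unit's incoming weight vector of the final
    dense layer onto the L2 ball of radius ``c`` (default from config)."""
    c = model.cfg.max_norm_dense if c is None else c
    model.head.weight.data = max_norm_rescale(model.head.weight.data, c, axis=0)


def save_model(model: MSATModel, path: str) -> None:
    """Persist config + weights (JSON + NPZ) under directory ``path``."""
    os.makedirs(path, exist_ok=True)
    meta = {
        "config": _config_to_dict(model.cfg),
        "n_channels": model.n_channels,
        "n_samples": model.n_samples,
        "has_adapter": model.adapter is not None,
    }
    with open(os.path.join(path, "model.json"), "w") as f:
        json.dump(meta, f, indent=2)
    state = model.state_dict()
    bn_stats = {}
    for i, m in enumerate(model.modules()):
        if hasattr(m, "running_mean"):
            bn_stats[f"bn{i}_mean"] = m.running_mean
            bn_stats[f"bn{i}_var"] = m.running_var
    np.savez(os.path.join(path, "weights.npz"), **state, **bn_stats)


def load_model(path: str) -> MSATModel:
    with open(os.path.join(path, "model.json")) as f:
        meta = json.load(f)
    cfg = _config_from_dict(meta["config"])
    model = build_model(cfg, meta["n_channels"], meta["n_samples"], seed=0)
    if meta["has_adapter"] and model.adapter is None:
        from .subject_adapter import insert_adapters

        insert_adapters(model)
    archive = np.load(os.path.join(path, "weights.npz"))
    state = {k: archive[k] for k in archive.files if not k.startswith(("bn", "__"))}
    model.load_state_dict(state)
    for i, m in enumerate(model.modules()):
        if hasattr(m, "running_mean"):
            m.running_mean = archive[f"bn{i}_mean"]
            m.running_var = archive[f"bn{i}_var"]
    return model


def _config_to_dict(cfg: MSATConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _config_from_dict(d: dict) -> MSATConfig:
    d = dict(d)
    d["msfe"] = MSFEConfig(**d["msfe"])
    d["decoder"] = TemporalDecoderConfig(**d["decoder"])
    if d.get("adapter"):
        d["adapter"] = AdapterConfig(**d["adapter"])
    return MSATConfig(**d)
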