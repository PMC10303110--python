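"""Training loops and the within-/cross-subject evaluation protocols.

Within-subject: train on one session set, early-stop on a stratified
validation split of the training data, evaluate once on the held-out
session set.

Cross-subject, four steps: (1) pick a target subject; half of its
trials (class-stratified) fine-tune, the other half evaluates;
(2) pre-train on the pooled remaining subjects, all parameters
trainable; (3) insert identity-at-init adapters and fine-tune only
their parameters on the target's fine-tuning half; (4) evaluate on the
target's held-out half, asserting the backbone stayed bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .data_io import EpochSet
from .model import MSATConfig, MSATModel, apply_max_norm, build_model, predict
from .nn import Adam, Tensor
from .nn.functional import log_softmax
from .subject_adapter import freeze_all_but_adapters, insert_adapters

__all__ = [
    "TrainConfig",
    "FitReport",
    "train_within_subject",
    "run_cross_subject",
    "evaluate",
    "fit",
    "concat_epochs",
]


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 0.0008
    optimizer: str = "adam"
    max_epochs: int = 1000
    early_stop_patience: int = 50
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.early_stop_patience > 0 and not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1) when early stopping is enabled")


@dataclass
class FitReport:
    epoch_losses: list[float]
    stopped_epoch: int
    test_accuracy: float
    confusion: np.ndarray
    parameter_audit: dict[str, int]
    config_hash: str
    val_losses: list[float] = field(default_factory=list)
    baseline_accuracy: float | None = None  # frozen model, cross-subject runs only
    source_accuracy: float | None = None  # pre-training fit on the pooled source

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confusion"] = np.asarray(self.confusion).tolist()
        return d


def _config_hash(*cfgs) -> str:
    payload = json.dumps([dataclasses.asdict(c) for c in cfgs], sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def _stratified_indices(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """(held_out, rest) index arrays; ``fraction`` of each class held out."""
    held, rest = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        k = max(1, int(round(fraction * idx.size)))
        held.append(idx[:k])
        rest.append(idx[k:])
    return np.sort(np.concatenate(held)), np.sort(np.concatenate(rest))


def cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    lsm = log_softmax(logits, axis=-1)
    picked = lsm[np.arange(len(y)), y]
    return -picked.mean()


def _epoch_loss(model: MSATModel, X: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    from .nn import no_grad

    was_training = model.training
    model.eval()
    total = 0.0
    batch_size = max(batch_size, 256)  # inference-only pass; large batches amortize overhead
    try:
        with no_grad():
            for i in range(0, len(y), batch_size):
                xb, yb = X[i : i + batch_size], y[i : i + batch_size]
                total += float(cross_entropy(model(xb), yb).data) * len(yb)
    finally:
        model.train(was_training)
    return total / len(y)


def _apply_mode(model: MSATModel, backbone_eval: bool) -> None:
    if backbone_eval:
        # adapter fine-tuning: backbone batch-norm statistics and dropout
        # must not move, only the adapter trains
        model.eval()
        if model.adapter is not None:
            model.adapter.train(True)
        model.training = True
    else:
        model.train()


def fit(
    model: MSATModel,
    train: EpochSet,
    tc: TrainConfig,
    max_norm: bool = True,
    backbone_eval: bool = False,
) -> tuple[list[float], list[float], int]:
    """Minibatch Adam training with early stopping and best-weight restore.

    Returns (train losses, validation losses, stopped epoch).
    """
    rng = np.random.default_rng(tc.seed)
    X = train.data.astype(np.float32)
    y = train.labels
    use_val = tc.early_stop_patience > 0
    if use_val:
        val_idx, tr_idx = _stratified_indices(y, tc.val_fraction, rng)
        X_val, y_val = X[val_idx], y[val_idx]
        X, y = X[tr_idx], y[tr_idx]
    opt = Adam(model.parameters(), lr=tc.learning_rate)
    losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_state = None
    best_stats = None
    patience_left = tc.early_stop_patience
    stopped = tc.max_epochs - 1
    for epoch in range(tc.max_epochs):
        _apply_mode(model, backbone_eval)
        order = rng.permutation(len(y))
        epoch_loss = 0.0
        for i in range(0, len(order), tc.batch_size):
            idx = order[i : i + tc.batch_size]
            logits = model(X[idx])
            loss = cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            if max_norm:
                apply_max_norm(model)
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / len(y))
        if use_val:
            vl = _epoch_loss(model, X_val, y_val, tc.batch_size)
            val_losses.append(vl)
            if vl < best_val - 1e-6:
                best_val = vl
                best_state = model.state_dict()
                best_stats = _bn_stats(model)
                patience_left = tc.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    stopped = epoch
                    break
        stopped = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
        _restore_bn_stats(model, best_stats)
    return losses, val_losses, stopped


def _bn_stats(model) -> list[tuple[np.ndarray, np.ndarray]]:
    return [
        (m.running_mean.copy(), m.running_var.copy())
        for m in model.modules()
        if hasattr(m, "running_mean")
    ]


def _restore_bn_stats(model, stats) -> None:
    mods = [m for m in model.modules() if hasattr(m, "running_mean")]
    for m, (mean, var) in zip(mods, stats):
        m.running_mean = mean
        m.running_var = var


def evaluate(model: MSATModel, test: EpochSet) -> tuple[float, np.ndarray]:
    """(accuracy, confusion) where confusion[i, j] counts true=i, pred=j."""
    if test.n_trials == 0:
        raise ValueError("cannot evaluate on an empty test set")
    preds, _ = predict(model, test)
    n = test.n_classes
    confusion = np.zeros((n, n), dtype=np.int64)
    np.add.at(confusion, (test.labels, preds), 1)
    accuracy = float(np.trace(confusion) / confusion.sum())
    return accuracy, confusion


def _check_compatible(a: EpochSet, b: EpochSet) -> None:
    if a.n_channels != b.n_channels or a.n_samples != b.n_samples:
        raise ValueError("train/test shapes differ")
    if list(a.class_names) != list(b.class_names):
        raise ValueError(
            f"class coding mismatch: {a.class_names} vs {b.class_names}"
        )


def train_within_subject(
    train: EpochSet,
    test: EpochSet,
    model_cfg: MSATConfig,
    tc: TrainConfig,
) -> tuple[MSATModel, FitReport]:
    """Same-subject protocol: no adapter, train on one session set,
    evaluate on the other."""
    if model_cfg.adapter is not None:
        raise ValueError("the within-subject protocol does not use the subject adapter")
    _check_compatible(train, test)
    model = build_model(model_cfg, train.n_channels, train.n_samples, seed=tc.seed)
    losses, val_losses, stopped = fit(model, train, tc)
    accuracy, confusion = evaluate(model, test)
    report = FitReport(
        epoch_losses=losses,
        stopped_epoch=stopped,
        test_accuracy=accuracy,
        confusion=confusion,
        parameter_audit=model.parameter_audit(),
        config_hash=_config_hash(model_cfg, tc),
        val_losses=val_losses,
    )
    return model, report


def concat_epochs(sets: list[EpochSet], subject_id: str = "pooled") -> EpochSet:
    """Pool trials from several subjects (shapes and class coding must match)."""
    first = sets[0]
    for other in sets[1:]:
        _check_compatible(first, other)
    return EpochSet(
        data=np.concatenate([s.data for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        fs=first.fs,
        channel_names=list(first.channel_names),
        subject_id=subject_id,
        session_ids=np.concatenate([np.full(s.n_trials, i + 1) for i, s in enumerate(sets)]),
        class_names=list(first.class_names),
    )


def run_cross_subject(
    cohort: list[EpochSet],
    target_index: int,
    model_cfg: MSATConfig,
    tc: TrainConfig,
    finetune_tc: TrainConfig | None = None,
    seed: int = 0,
    adapter_cfg=None,
    finetune_restarts: int = 1,
) -> tuple[MSATModel, FitReport]:
    """Four-step transfer protocol (see module docstring).

    ``finetune_restarts`` > 1 repeats the adapter fine-tuning from
    fresh adapter initializations and keeps the restart with the lowest
    validation loss on the fine-tuning half (standard restart-based
    model selection; the evaluation half is never consulted).
    """
    if len(cohort) < 2:
        raise ValueError("cross-subject protocol needs a cohort of at least 2 subjects")
    if not 0 <= target_index < len(cohort):
        raise ValueError(f"target_index {target_index} out of range for {len(cohort)} subjects")
    if model_cfg.adapter is not None:
        raise ValueError("adapters are inserted by the protocol; leave model_cfg.adapter unset")
    if finetune_tc is None:
        finetune_tc = dataclasses.replace(tc, max_epochs=100, early_stop_patience=20)

    target = cohort[target_index]
    sources = [s for i, s in enumerate(cohort) if i != target_index]

    # step 1: class-stratified half split of the target subject
    rng = np.random.default_rng(seed)
    eval_idx, tune_idx = _stratified_indices(target.labels, 0.5, rng)
    assert not set(eval_idx) & set(tune_idx)
    target_tune = target.select(tune_idx)
    target_eval = target.select(eval_idx)

    # step 2: pre-train on the pooled source domain, all parameters trainable
    pooled = concat_epochs(sources, subject_id="source-pool")
    model = build_model(model_cfg, pooled.n_channels, pooled.n_samples, seed=tc.seed)
    losses, val_losses, stopped = fit(model, pooled, tc)
    source_accuracy, _ = evaluate(model, pooled)
    baseline_accuracy, _ = evaluate(model, target_eval)

    # step 3: adapters in (identity at init), backbone frozen, fine-tune
    insert_adapters(model, cfg=adapter_cfg, seed=seed)
    freeze_all_but_adapters(model)
    backbone_before = {
        name: p.data.copy()
        for name, p in model.named_parameters()
        if not name.startswith("adapter.")
    }
    used_adapter_cfg = model.adapter.cfg
    best_state = None
    best_score = np.inf
    ft_losses: list[float] = []
    for restart in range(max(1, finetune_restarts)):
        if restart:
            model.adapter = None
            insert_adapters(model, cfg=used_adapter_cfg, seed=seed + 1009 * restart)
            freeze_all_but_adapters(model)
        losses_r, val_r, _ = fit(
            model, target_tune, finetune_tc, max_norm=False, backbone_eval=True
        )
        score = min(val_r) if val_r else losses_r[-1]
        if score < best_score:
            best_score = score
            best_state = model.adapter.state_dict()
            ft_losses = losses_r
    model.adapter.load_state_dict(best_state)

    # step 4: evaluate on the held-out target half; backbone must be untouched
    for name, p in model.named_parameters():
        if not name.startswith("adapter."):
            delta = np.abs(p.data - backbone_before[name]).max()
            if delta != 0:
                raise AssertionError(f"frozen parameter {name} changed by {delta}")
    accuracy, confusion = evaluate(model, target_eval)
    report = FitReport(
        epoch_losses=losses + ft_losses,
        stopped_epoch=stopped,
        test_accuracy=accuracy,
        confusion=confusion,
        parameter_audit=model.parameter_audit(),
        config_hash=_config_hash(model_cfg, tc, finetune_tc),
        val_losses=val_losses,
        baseline_accuracy=baseline_accuracy,
        source_accuracy=source_accuracy,
    )
    return model, report
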