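"""Synthetic motor-imagery-like EEG with controllable class separability.

Trials are 1/f background noise plus mu- and beta-band sinusoidal
rhythms at every channel.  A class is encoded by event-related
desynchronization (ERD): the rhythm amplitude at that class's channels
is multiplied by ``1 - erd_depth``.  Per-subject spectral peaks, channel
gains, and noise level emulate between-subject variability, so the
cross-subject transfer machinery can be exercised without real
recordings.

All generation is a pure function of (parameters, seed): each trial
draws from a dedicated ``default_rng([seed, trial_index])`` substream,
so results do not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .data_io import EpochSet

__all__ = [
    "SubjectModel",
    "ClassEffect",
    "DEFAULT_MONTAGE",
    "DEFAULT_EFFECTS_4CLASS",
    "DEFAULT_EFFECTS_2CLASS",
    "generate_subject",
    "draw_subject_models",
    "generate_cohort",
    "band_power",
    "bandpower_features",
    "linear_probe_accuracy",
]

# 10-20 subset matching a 22-channel motor-imagery montage
DEFAULT_MONTAGE = [
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
]

MU_BAND = (8.0, 13.0)
BETA_BAND = (18.0, 26.0)

# amplitude constants, microvolts
_NOISE_RMS = 4.0
_MU_AMP = 3.0
_BETA_AMP = 1.5


@dataclass
class SubjectModel:
    """Per-subject generative parameters."""

    subject_id: str
    channel_gains: np.ndarray
    mu_peak_hz: float = 10.0
    beta_peak_hz: float = 22.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if not (6.0 <= self.mu_peak_hz <= 14.0):
            raise ValueError(f"mu_peak_hz must lie in [6, 14], got {self.mu_peak_hz}")
        if not (15.0 <= self.beta_peak_hz <= 30.0):
            raise ValueError(f"beta_peak_hz must lie in [15, 30], got {self.beta_peak_hz}")
        if np.any(self.channel_gains <= 0):
            raise ValueError("all channel gains must be positive")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")


@dataclass
class ClassEffect:
    """ERD signature of one class: which channels desynchronize, and how much."""

    class_id: int
    erd_channels: list[str] = field(default_factory=list)
    erd_depth: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must lie in [0, 1], got {self.erd_depth}")


# contralateral ERD convention: left hand -> C4, right hand -> C3,
# feet -> Cz, tongue -> C3+C4
def DEFAULT_EFFECTS_4CLASS(erd_depth: float = 0.8) -> list[ClassEffect]:
    return [
        ClassEffect(0, ["C4"], erd_depth),
        ClassEffect(1, ["C3"], erd_depth),
        ClassEffect(2, ["Cz"], erd_depth),
        ClassEffect(3, ["C3", "C4"], erd_depth),
    ]


def DEFAULT_EFFECTS_2CLASS(erd_depth: float = 0.8) -> list[ClassEffect]:
    return [ClassEffect(0, ["C4"], erd_depth), ClassEffect(1, ["C3"], erd_depth)]


def _one_over_f_noise(rng: np.random.Generator, C: int, T: int) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum, unit RMS, shape [C, T]."""
    n_freq = T // 2 + 1
    freqs = np.arange(n_freq, dtype=float)
    shape = np.zeros(n_freq)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((C, n_freq)) + 1j * rng.standard_normal((C, n_freq))) * shape
    x = np.fft.irfft(spec, n=T, axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / np.maximum(rms, 1e-12)


def _validate_effects(effects: list[ClassEffect], channel_names: list[str]) -> list[ClassEffect]:
    ids = [e.class_id for e in effects]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate class_ids in effects: {sorted(ids)}")
    if sorted(ids) != list(range(len(ids))):
        raise ValueError(f"class_ids must be contiguous from 0, got {sorted(ids)}")
    known = set(channel_names)
    for e in effects:
        unknown = [c for c in e.erd_channels if c not in known]
        if unknown:
            raise ValueError(f"unknown erd channel name(s) {unknown} for class {e.class_id}")
    return sorted(effects, key=lambda e: e.class_id)


def generate_subject(
    sm: SubjectModel,
    effects: list[ClassEffect],
    n_per_class: int,
    fs: float = 250.0,
    T: int = 1000,
    channel_names: list[str] | None = None,
) -> EpochSet:
    """Generate one subject's balanced labelled trials, [K, C, T].

    K = n_classes * n_per_class.  Deterministic given ``sm.seed``.
    Trials of each class are split across session ids 1 and 2 so the
    within-subject session split applies directly.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    channel_names = list(channel_names) if channel_names is not None else list(DEFAULT_MONTAGE)
    C = len(channel_names)
    if len(sm.channel_gains) != C:
        raise ValueError(
            f"channel_gains length {len(sm.channel_gains)} != number of channels {C}"
        )
    effects = _validate_effects(effects, channel_names)
    n_classes = len(effects)
    ch_index = {name: i for i, name in enumerate(channel_names)}
    t = np.arange(T) / fs

    K = n_classes * n_per_class
    data = np.empty((K, C, T), dtype=np.float64)
    labels = np.empty(K, dtype=np.int64)
    session_ids = np.empty(K, dtype=np.int64)
    trial = 0
    for e in effects:
        erd_idx = np.array([ch_index[c] for c in e.erd_channels], dtype=int)
        for j in range(n_per_class):
            rng = np.random.default_rng([int(sm.seed) & 0x7FFFFFFF, trial])
            x = _one_over_f_noise(rng, C, T) * (_NOISE_RMS * sm.noise_scale)
            mu_amp = np.full(C, _MU_AMP)
            beta_amp = np.full(C, _BETA_AMP)
            if erd_idx.size:
                mu_amp[erd_idx] *= 1.0 - e.erd_depth
                beta_amp[erd_idx] *= 1.0 - e.erd_depth
            phase_mu = rng.uniform(0, 2 * np.pi, size=(C, 1))
            phase_beta = rng.uniform(0, 2 * np.pi, size=(C, 1))
            x += mu_amp[:, None] * np.sin(2 * np.pi * sm.mu_peak_hz * t[None, :] + phase_mu)
            x += beta_amp[:, None] * np.sin(2 * np.pi * sm.beta_peak_hz * t[None, :] + phase_beta)
            x *= sm.channel_gains[:, None]
            data[trial] = x
            labels[trial] = e.class_id
            session_ids[trial] = 1 if j < (n_per_class + 1) // 2 else 2
            trial += 1

    return EpochSet(
        data=data.astype(np.float32),
        labels=labels,
        fs=fs,
        channel_names=channel_names,
        subject_id=sm.subject_id,
        session_ids=session_ids,
        class_names=[f"class{i}" for i in range(n_classes)],
    )


def draw_subject_models(
    n_subjects: int,
    n_channels: int,
    shift_scale: float,
    seed: int,
    base_noise_scale: float = 1.0,
) -> list[SubjectModel]:
    """Draw per-subject parameters; dispersion scales with ``shift_scale``.

    shift_scale = 0 yields identical subjects (up to subject ids/seeds).
    """
    models = []
    for i in range(n_subjects):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 104729, i])

        def offset(lo, spread):
            # every subject is displaced from the population centre by at
            # least ``lo`` (scaled), in a random direction: a cohort at
            # shift_scale > 0 has no accidentally-unshifted member, while
            # shift_scale = 0 still collapses to identical subjects
            return shift_scale * rng.choice([-1.0, 1.0]) * (lo + spread * abs(rng.standard_normal()))

        mu = float(np.clip(10.0 + 1.2 * shift_scale * rng.standard_normal(), 6.5, 13.5))
        beta = float(np.clip(22.0 + 1.5 * shift_scale * rng.standard_normal(), 15.5, 29.5))
        # a shared gain factor (montage/impedance differences) plus a mild
        # per-channel spread; keeping the per-channel part small keeps the
        # spatial class contrast recoverable for the target subject
        global_gain = np.exp(0.25 * shift_scale * rng.standard_normal())
        gains = global_gain * np.exp(0.2 * shift_scale * rng.standard_normal(n_channels))
        noise = float(base_noise_scale * np.exp(offset(0.1, 0.25)))
        models.append(
            SubjectModel(
                subject_id=f"S{i + 1}",
                channel_gains=gains,
                mu_peak_hz=mu,
                beta_peak_hz=beta,
                noise_scale=noise,
                seed=int(np.random.default_rng([int(seed) & 0x7FFFFFFF, 15485863, i]).integers(2**31)),
            )
        )
    return models


def generate_cohort(
    n_subjects: int,
    base_effects: list[ClassEffect],
    shift_scale: float,
    seed: int,
    n_per_class: int = 72,
    fs: float = 250.0,
    T: int = 1000,
    channel_names: list[str] | None = None,
    base_noise_scale: float = 1.0,
) -> list[EpochSet]:
    """One EpochSet per subject, sharing class effects but differing in
    subject parameters with dispersion ``shift_scale``."""
    if n_subjects < 2:
        raise ValueError(f"a cohort needs at least 2 subjects, got {n_subjects}")
    channel_names = list(channel_names) if channel_names is not None else list(DEFAULT_MONTAGE)
    models = draw_subject_models(
        n_subjects, len(channel_names), shift_scale, seed, base_noise_scale=base_noise_scale
    )
    return [
        generate_subject(sm, base_effects, n_per_class, fs=fs, T=T, channel_names=channel_names)
        for sm in models
    ]


def band_power(es: EpochSet, band: tuple[float, float]) -> np.ndarray:
    """Mean Welch power in ``band`` per trial and channel, shape [K, C]."""
    nperseg = min(es.n_samples, int(es.fs))
    freqs, psd = signal.welch(es.data, fs=es.fs, nperseg=nperseg, axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return psd[..., sel].mean(axis=-1)


def bandpower_features(es: EpochSet, bands=(MU_BAND, BETA_BAND)) -> np.ndarray:
    """Log band-power features [K, C * n_bands] for simple probes."""
    feats = [np.log(band_power(es, b) + 1e-12) for b in bands]
    return np.concatenate(feats, axis=1)


def linear_probe_accuracy(train: EpochSet, test: EpochSet, C_reg: float = 1.0) -> float:
    """Accuracy of a regularized linear model on band-power features.

    Serves as the fixed reference classifier for the separability dial.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    Xtr, Xte = bandpower_features(train), bandpower_features(test)
    scaler = StandardScaler().fit(Xtr)
    clf = LogisticRegression(C=C_reg, max_iter=2000)
    clf.fit(scaler.transform(Xtr), train.labels)
    return float(clf.score(scaler.transform(Xte), test.labels))
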