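"""Labelled EEG trial containers, archive I/O, and session-based splits."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import h5py

__all__ = [
    "EpochSet",
    "SplitSpec",
    "save_epochs",
    "load_epochs",
    "split_by_session",
    "load_gdf_dataset",
    "FormatError",
]

# EOG channel names used by the 2a competition recordings
EOG_2A = ["EOG-left", "EOG-central", "EOG-right"]
EOG_2B = ["EOG:ch01", "EOG:ch02", "EOG:ch03"]


class FormatError(ValueError):
    """Raised when an archive or recording does not match the expected layout."""


@dataclass
class EpochSet:
    """Epoched multi-channel EEG trials with labels and metadata.

    data: [K trials, C channels, T samples] in microvolts.
    labels: integer class per trial, 0-based and contiguous.
    session_ids: recording session each trial came from.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = "unknown"
    session_ids: np.ndarray | None = None
    class_names: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be [K, C, T], got shape {self.data.shape}")
        K, C, T = self.data.shape
        if T < 1:
            raise ValueError("trials must contain at least one sample")
        if self.labels.shape != (K,):
            raise ValueError(f"labels length {self.labels.shape} != K={K}")
        if self.session_ids is None:
            self.session_ids = np.ones(K, dtype=np.int64)
        self.session_ids = np.asarray(self.session_ids, dtype=np.int64)
        if self.session_ids.shape != (K,):
            raise ValueError(f"session_ids length {self.session_ids.shape} != K={K}")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != C:
            raise ValueError(f"channel_names length {len(self.channel_names)} != C={C}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if K and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.class_names is None:
            n = int(self.labels.max()) + 1 if K else 0
            self.class_names = [f"class{i}" for i in range(n)]
        if K and int(self.labels.max()) >= len(self.class_names):
            raise ValueError("label exceeds number of class names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset of trials, preserving class coding."""
        return replace(
            self,
            data=self.data[mask],
            labels=self.labels[mask],
            session_ids=self.session_ids[mask],
            channel_names=list(self.channel_names),
            class_names=list(self.class_names),
        )


@dataclass
class SplitSpec:
    """Which sessions feed the train/test sides, and channels to drop."""

    train_sessions: set = field(default_factory=set)
    test_sessions: set = field(default_factory=set)
    drop_channels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.train_sessions = set(int(s) for s in self.train_sessions)
        self.test_sessions = set(int(s) for s in self.test_sessions)
        overlap = self.train_sessions & self.test_sessions
        if overlap:
            raise ValueError(f"train and test sessions overlap: {sorted(overlap)}")


# 2a convention: session 1 trains, session 2 tests; 2b: 1-3 train, 4-5 test
SPLIT_2A = SplitSpec(train_sessions={1}, test_sessions={2}, drop_channels=EOG_2A)
SPLIT_2B = SplitSpec(train_sessions={1, 2, 3}, test_sessions={4, 5}, drop_channels=EOG_2B)

_REQUIRED_KEYS = ("data", "labels", "fs", "channel_names", "subject_id", "session_ids")


def save_epochs(es: EpochSet, path) -> None:
    """Write an EpochSet to a self-describing HDF5 archive (float32 data)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=es.data.astype(np.float32))
        f.create_dataset("labels", data=es.labels)
        f.create_dataset("session_ids", data=es.session_ids)
        f.attrs["fs"] = float(es.fs)
        f.attrs["subject_id"] = es.subject_id
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("channel_names", data=np.array(es.channel_names, dtype=object), dtype=str_dt)
        f.create_dataset("class_names", data=np.array(es.class_names, dtype=object), dtype=str_dt)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for key in _REQUIRED_KEYS:
            if key not in f and key not in f.attrs:
                raise FormatError(f"epoch archive missing required key: {key!r}")
        return EpochSet(
            data=f["data"][...],
            labels=f["labels"][...],
            fs=float(f.attrs["fs"]),
            channel_names=[c.decode() if isinstance(c, bytes) else str(c) for c in f["channel_names"][...]],
            subject_id=str(f.attrs["subject_id"]),
            session_ids=f["session_ids"][...],
            class_names=[c.decode() if isinstance(c, bytes) else str(c) for c in f["class_names"][...]]
            if "class_names" in f
            else None,
        )


def split_by_session(es: EpochSet, spec: SplitSpec) -> tuple[EpochSet, EpochSet]:
    """Partition trials into train/test by session id."""
    present = set(int(s) for s in np.unique(es.session_ids))
    missing = (spec.train_sessions | spec.test_sessions) - present
    if missing:
        raise ValueError(f"sessions {sorted(missing)} not present in data (have {sorted(present)})")
    train_mask = np.isin(es.session_ids, sorted(spec.train_sessions))
    test_mask = np.isin(es.session_ids, sorted(spec.test_sessions))
    if not train_mask.any() or not test_mask.any():
        raise ValueError("session split produced an empty train or test set")
    return es.select(train_mask), es.select(test_mask)


def load_gdf_dataset(path, layout: str = "2a", window: tuple[float, float] = (0.0, 4.0)) -> EpochSet:
    """Epoch a GDF recording laid out like the BCI Competition IV 2a/2b files.

    ``window`` is (start, stop) in seconds relative to cue onset; the
    default covers the 4 s imagination period.  Requires the optional
    ``mne`` dependency.  EOG channels are dropped and event codes are
    remapped to 0-based contiguous labels.
    """
    import os

    if layout not in ("2a", "2b"):
        raise ValueError(f"layout must be '2a' or '2b', got {layout!r}")
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise ValueError(f"window must have positive length, got ({t0}, {t1})")
    if not os.path.exists(path):
        raise FileNotFoundError(f"GDF file not found: {path}")
    try:
        import mne
    except ImportError as e:  # pragma: no cover - exercised only without mne
        raise ImportError(
            "reading GDF files requires the optional 'mne' dependency "
            "(pip install msatnet[gdf])"
        ) from e

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    drop = EOG_2A if layout == "2a" else EOG_2B
    raw.drop_channels([c for c in drop if c in raw.ch_names])
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    # cue codes in the competition annotation scheme
    cue_names = ("769", "770", "771", "772") if layout == "2a" else ("769", "770")
    cue_id = {name: event_id[name] for name in cue_names if name in event_id}
    if not cue_id:
        raise FormatError(
            f"no cue event codes {cue_names} found; file defines {sorted(event_id)}"
        )
    fs = float(raw.info["sfreq"])
    n_total = raw.n_times
    sel = np.isin(events[:, 2], list(cue_id.values()))
    onsets = events[sel, 0]
    codes = events[sel, 2]
    lo = onsets + int(round(t0 * fs))
    hi = onsets + int(round(t1 * fs))
    if (lo < 0).any() or (hi > n_total).any():
        raise ValueError("epoch window exceeds recording bounds for at least one trial")
    sig = raw.get_data() * 1e6  # volts -> microvolts
    data = np.stack([sig[:, a:b] for a, b in zip(lo, hi)])
    code_order = sorted(set(codes))
    label_map = {c: i for i, c in enumerate(code_order)}
    labels = np.array([label_map[c] for c in codes])
    inv_event = {v: k for k, v in cue_id.items()}
    class_names = [inv_event[c] for c in code_order]
    return EpochSet(
        data=data,
        labels=labels,
        fs=fs,
        channel_names=list(raw.ch_names),
        subject_id=os.path.basename(str(path)),
        session_ids=np.ones(len(labels), dtype=np.int64),
        class_names=class_names,
    )
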