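import numpy as np
import pytest

from msatnet.data_io import EpochSet
from msatnet import synthetic_eeg as se

# small montage used by training-speed-sensitive tests
SMALL_CHANNELS = ["C3", "Cz", "C4", "Fz"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_epochs():
    """8 trials, 3 channels, 100 samples, 2 classes."""
    gen = np.random.default_rng(0)
    return EpochSet(
        data=gen.normal(size=(8, 3, 100)).astype(np.float32),
        labels=np.array([0, 1] * 4),
        fs=250.0,
        channel_names=["C3", "Cz", "C4"],
        subject_id="T1",
        session_ids=np.array([1, 1, 1, 1, 2, 2, 2, 2]),
        class_names=["left", "right"],
    )


def make_subject(seed=1, n_per_class=20, T=250, depth=0.8, channels=SMALL_CHANNELS,
                 noise_scale=1.0, n_classes=4):
    effects = (
        se.DEFAULT_EFFECTS_4CLASS(depth) if n_classes == 4 else se.DEFAULT_EFFECTS_2CLASS(depth)
    )
    sm = se.SubjectModel(
        f"S{seed}", np.ones(len(channels)), noise_scale=noise_scale, seed=seed
    )
    return se.generate_subject(sm, effects, n_per_class, fs=250.0, T=T, channel_names=channels)
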