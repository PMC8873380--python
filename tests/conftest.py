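import numpy as np
import pytest

from eegpref.epochs import EpochSet, Montage


@pytest.fixture
def tiny_montage() -> Montage:
    """Six channels: two symmetric pairs plus two midline channels."""
    return Montage(
        channel_names=("L1", "R1", "L2", "R2", "M1", "M2"),
        pairs=(("L1", "R1"), ("L2", "R2")),
        midline=("M1", "M2"),
    )


def make_epochs(
    n_epochs: int = 4,
    n_channels: int = 6,
    n_samples: int = 1126,
    sfreq: float = 512.0,
    t0: float = -0.2,
    seed: int = 0,
    channel_names: tuple[str, ...] | None = None,
) -> EpochSet:
    rng = np.random.default_rng(seed)
    if channel_names is None:
        channel_names = tuple(f"C{i}" for i in range(n_channels))
    data = rng.standard_normal((n_epochs, len(channel_names), n_samples))
    subjects = np.array([f"S{i % 3}" for i in range(n_epochs)], dtype=object)
    return EpochSet(
        data=data,
        sfreq=sfreq,
        t0_offset=t0,
        channel_names=channel_names,
        subject_ids=subjects,
    )


@pytest.fixture
def random_epochs() -> EpochSet:
    return make_epochs()
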