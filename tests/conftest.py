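import numpy as np
import pytest

from sbcnn.net import NetworkConfig
from sbcnn.io import Session, N_CHANNELS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mini_config():
    """A miniature network small enough for brute-force/finite-difference work."""
    return NetworkConfig(
        n_channels=3,
        window=6,
        conv1_filters=4,
        conv1_size=3,
        conv2_filters=4,
        conv2_size=3,
        pool_kernel=2,
        pool_stride=2,
        pl1_outputs=5,
        n_classes=3,
    )


@pytest.fixture
def random_session(rng):
    """A short labelled session with a class switch at frame 40."""
    n = 80
    values = rng.gamma(2.0, 0.5, size=(n, N_CHANNELS))
    labels = np.where(np.arange(n) < 40, 2, 7)
    return Session(values, labels=labels)
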