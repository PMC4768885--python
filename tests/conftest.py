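import numpy as np
import pytest

import trapcam as tc


@pytest.fixture(scope="session")
def noiseless_stack():
    """Small noiseless sequence with fly dynamics and ground truth."""
    cfg = tc.SimConfig(
        n_frames=120, seed=11, noise_sd=0.0, arrival_rate=0.1, departure_rate=0.05
    )
    return tc.generate_image_sequence(cfg)


@pytest.fixture(scope="session")
def capture_counts():
    return tc.load_capture_counts()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
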