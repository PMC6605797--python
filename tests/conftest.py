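import numpy as np
import pytest

from wpbq.synthgen import SyntheticConfig, generate_image


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_noisefree():
    """One deterministic noise-free two-cell image with ground truth."""
    cfg = SyntheticConfig(seed=7, vesicle_shape="spot", noise_sd=0.0)
    return generate_image(cfg)


@pytest.fixture(scope="session")
def small_noisy():
    """The same layout with read noise applied."""
    cfg = SyntheticConfig(seed=7, vesicle_shape="spot", noise_sd=20.0)
    return generate_image(cfg)
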