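import numpy as np
import pytest

from cmapfusion import generate_dataset, preset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_config():
    return preset("toy")


@pytest.fixture(scope="session")
def small_dataset():
    """A small strong-signal dataset for fast structural tests."""
    cfg = preset("toy")
    cfg.data.n_samples = 80
    return generate_dataset(cfg.data)
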