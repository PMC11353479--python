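import numpy as np
import pytest

from facps import phantom


@pytest.fixture(scope="session")
def tiny_cfg():
    """A tiny phantom configuration for fast unit tests."""
    return phantom.PhantomConfig(image_size=32, n_classes=3, n_train=6, n_test=2,
                                 seed=7)


@pytest.fixture(scope="session")
def tiny_ds(tiny_cfg):
    return phantom.generate_dataset(tiny_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
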