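import numpy as np
import pytest

from fuzzylogit.datasets import generate, preset_dataset_I


@pytest.fixture(scope="session")
def dataset_I():
    """One realisation of the imbalanced + separated two-predictor design."""
    return generate(preset_dataset_I().with_seed(0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_quasi_separated():
    """1-predictor data perfectly separated at x=0 with a positive margin."""
    x = np.concatenate([np.linspace(-3.0, -0.5, 12), np.linspace(0.5, 3.0, 8)])
    y = (x > 0).astype(int)
    return x[:, None], y
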