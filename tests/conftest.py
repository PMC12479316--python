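import numpy as np
import pytest

from attnfnet.config import tiny_experiment_config
from attnfnet.synthetic import generate_dataset
from attnfnet.training import prepare_data


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Six subjects, three poses each, at the small 64x56 depth resolution."""
    return generate_dataset(6, 3, seed=11, grid_shape=(64, 56))


@pytest.fixture(scope="session")
def small_prepared(small_dataset):
    cfg = tiny_experiment_config(11)
    return prepare_data(small_dataset, cfg.preprocess)
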