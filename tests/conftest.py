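import numpy as np
import pytest

from ergan import dataio
from ergan import fixtures as fx


@pytest.fixture(scope="session")
def grid():
    return fx.DEFAULT_GRID


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small three-strength population reused by fast tests."""
    pop = fx.PopulationConfig(
        counts={1.204: (10, 10), 0.602: (10, 10), -0.367: (10, 10)},
        group_effect=0.8,
        seed=7,
    )
    return fx.generate_dataset(pop)


@pytest.fixture(scope="session")
def tiny_train(tiny_dataset):
    """Normalised train partition of the tiny population."""
    split = dataio.split_train_test(tiny_dataset, 0.25, seed=3)
    return dataio.normalize(split.train)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
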