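import numpy as np
import pandas as pd
import pytest

from floradyn import SimConfig, TraitSchema, TraitTable, make_benchmark


@pytest.fixture(scope="session")
def toy_traits():
    """Three species, one numeric + one categorical trait (hand-checkable)."""
    data = pd.DataFrame(
        {"size": [0.0, 5.0, 10.0], "color": ["red", "red", "blue"]},
        index=["A", "B", "C"],
    )
    return TraitTable(data, TraitSchema({"size": "numeric", "color": "categorical"}))


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark (8 assemblages x 6 plots x 4 years)."""
    return make_benchmark(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_config():
    """A desk-sized simulation config for fast end-to-end tests."""
    return SimConfig(n_pool=60, replicates=2, years=3, seed=11)


@pytest.fixture(scope="session")
def small_benchmark(small_config):
    return make_benchmark(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
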