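import numpy as np
import pytest

from markretain import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def small_params():
    """A 60-gene synthetic experiment, small enough for fast tests."""
    return SimulationParams(n_genes=60, genome_length=400_000, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
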