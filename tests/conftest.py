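import numpy as np
import pytest

from fpk.core import CutsiteTrack, GenomicInterval
from fpk.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_track(rng):
    region = GenomicInterval("chr1", 100, 400)
    return CutsiteTrack(region, rng.poisson(2.0, size=300).astype(float), kind="observed")
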