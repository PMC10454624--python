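import numpy as np
import pytest
from hypothesis import settings

from mockbench.synthetic_data import SimConfig, simulate_mock

settings.register_profile("ci", derandomize=True, max_examples=40)
settings.load_profile("ci")


SMALL_CONFIG = SimConfig(
    n_species=6,
    genome_length_range=(20_000, 40_000),
    ssu_copies_range=(1, 4),
    n_reads=400,
    seed=7,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A small mock bundle shared across tests (deterministic, seed 7)."""
    return simulate_mock(SMALL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
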