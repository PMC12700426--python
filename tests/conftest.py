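import numpy as np
import pytest

from sostempo.synthetic_data import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default conditions (shared, read-only)."""
    return generate_dataset(SimConfig(), seed=11, n_cells=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome for fast per-test generation."""
    return SimConfig(genome_length=80_000, n_genes=50, n_sos_genes=12)
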