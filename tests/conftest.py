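import numpy as np
import pytest
from hypothesis import settings

from nnice import synthetic as syn

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    return syn.SyntheticConfig(
        n_genes=300, n_cell_types=10, cells_per_type=30, marker_fold=5.0,
        dropout_rate=0.2, seed=11,
    )


@pytest.fixture(scope="session")
def small_signatures(small_config):
    return syn.generate_signatures(small_config)


@pytest.fixture(scope="session")
def small_reference(small_signatures, small_config):
    """300 genes x 300 labeled cells, 10 types."""
    return syn.simulate_cells(small_signatures, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
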