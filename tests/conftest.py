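import numpy as np
import pytest
from hypothesis import settings

from polyabind import synthetic as syn

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_config():
    return syn.SimConfig(n_genes=60, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return syn.generate_truth(small_config)


@pytest.fixture(scope="session")
def default_truth():
    """A full-size study at the default conditions (2000 genes)."""
    return syn.generate_truth(syn.SimConfig(n_genes=2000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
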