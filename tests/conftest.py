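import numpy as np
import pytest

from costsel.synthetic import SyntheticConfig, generate, worked_fixture


@pytest.fixture(scope="session")
def worked_table():
    """Two-genotype toy cohort with pooled survival rates {0.9, 0.5}."""
    return worked_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structurally complete synthetic experiment."""
    return generate(SyntheticConfig(n_genotypes=40, pots_per_genotype=3, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
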