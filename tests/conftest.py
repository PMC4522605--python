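import numpy as np
import pytest

from p5crkit.reference import synthetic_reference
from p5crkit.synthetic_data import (
    FamilyConfig,
    ToyStructureConfig,
    build_toy_assembly,
    simulate_family,
)


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference()


@pytest.fixture(scope="session")
def small_family():
    """8-taxon family at the default (moderate) divergence."""
    return simulate_family(FamilyConfig(n_taxa=8, seed=11))


@pytest.fixture()
def toy_assembly():
    return build_toy_assembly(ToyStructureConfig())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)
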