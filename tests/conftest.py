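import numpy as np
import pytest

from zebratox.chemio import fixture_molecule
from zebratox.synth import SynthConfig, make_dataset


@pytest.fixture(scope="session")
def mitc():
    """Methyl isothiocyanate, the canonical vectorization example."""
    return fixture_molecule("methyl_isothiocyanate")


@pytest.fixture(scope="session")
def methane():
    return fixture_molecule("methane")


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-chemical planted-signal dataset shared across tests."""
    return make_dataset(SynthConfig(n_chemicals=40, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
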