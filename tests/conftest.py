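import numpy as np
import pytest

from mvmol.chem_io import parse_and_canonicalize
from mvmol.synthetic_data import SynthesisSpec, gen_dataset, gen_molecules


@pytest.fixture(scope="session")
def benzene():
    return parse_and_canonicalize("c1ccccc1")


@pytest.fixture(scope="session")
def aspirin():
    return parse_and_canonicalize("CC(=O)Oc1ccccc1C(=O)O")


@pytest.fixture(scope="session")
def naphthalene():
    return parse_and_canonicalize("c1ccc2ccccc2c1")


@pytest.fixture(scope="session")
def small_library():
    """120 unlabeled synthetic molecules, deterministic."""
    return gen_molecules(SynthesisSpec(n_molecules=120, seed=7))


@pytest.fixture(scope="session")
def classification_table():
    """300 molecules labeled by nitro-group presence (prevalence 0.5)."""
    return gen_dataset(SynthesisSpec(n_molecules=300, seed=11))


@pytest.fixture(scope="session")
def regression_table():
    """200 molecules with noiseless descriptor-linear labels."""
    return gen_dataset(
        SynthesisSpec(
            n_molecules=200, seed=13, label_rule="descriptor_regression", noise_sd=0.0
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
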