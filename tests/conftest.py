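import numpy as np
import pytest

from geocofactor.mineral_chem import load_element_table
from geocofactor.coordination_sphere import (
    load_hydropathy_scale,
    load_ligand_registry,
    load_residue_aliases,
)


@pytest.fixture(scope="session")
def element_table():
    return load_element_table()


@pytest.fixture(scope="session")
def registry():
    return load_ligand_registry()


@pytest.fixture(scope="session")
def kd_scale():
    return load_hydropathy_scale()


@pytest.fixture(scope="session")
def aliases():
    return load_residue_aliases()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
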