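import numpy as np
import pytest

from consensusvs.data_io import CompoundRecord
from consensusvs.synthetic import SyntheticSpec, generate_compounds


@pytest.fixture(scope="session")
def small_bundle():
    """A 40-active / 120-decoy synthetic bundle shared across tests."""
    return generate_compounds(SyntheticSpec(n_actives=40, n_decoys=120, seed=7))


@pytest.fixture
def simple_records():
    return [
        CompoundRecord(id="eth", smiles="CCO", role="active", pic50=6.5),
        CompoundRecord(id="prop", smiles="CCCO", role="active", pic50=7.0),
        CompoundRecord(id="benz", smiles="c1ccccc1", role="active", pic50=5.0),
        CompoundRecord(id="tol", smiles="Cc1ccccc1", role="active", pic50=5.5),
        CompoundRecord(id="phen", smiles="Oc1ccccc1", role="active", pic50=6.0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
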