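import numpy as np
import pytest

from molhgt.datasets import generate_toy_dataset

# small, chemically diverse SMILES set used across graph tests
DIVERSE_SMILES = [
    "C",
    "CC",
    "CCO",
    "c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",  # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",  # paracetamol
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "CCOC(=O)c1ccccc1",  # ethyl benzoate
    "NC(=O)c1ccccc1",
    "C1CCOC1",
    "ClC(Cl)Cl",
    "CC(C)(C)OC(=O)NCCS",
    "O=S(=O)(N)c1ccc(Cl)cc1",
]


@pytest.fixture(scope="session")
def toy_table():
    return generate_toy_dataset(48, seed=11, task_type="regression")


@pytest.fixture(scope="session")
def toy_classification_table():
    return generate_toy_dataset(48, seed=11, task_type="classification")


@pytest.fixture(scope="session")
def fixture_smiles(toy_table):
    """Diverse hand-picked molecules plus generated multi-fragment ones."""
    return DIVERSE_SMILES + toy_table.smiles[:30]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
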