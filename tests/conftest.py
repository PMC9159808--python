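import numpy as np
import pytest
from rdkit import Chem
from sklearn.model_selection import train_test_split

from holopls import hologram as hg
from holopls import plsda
from holopls import synthetic_fixtures as sf
from holopls.molecule_io import standardize


def mol_from_smiles(smiles: str, mol_id: str = "m"):
    raw = Chem.MolFromSmiles(smiles)
    assert raw is not None, smiles
    return standardize(raw, mol_id)


@pytest.fixture(scope="session")
def default_spec():
    return sf.FixtureSpec(seed=17)


@pytest.fixture(scope="session")
def fixture_data(default_spec):
    return sf.generate_labeled_smiles(default_spec)


@pytest.fixture(scope="session")
def fixture_mols(fixture_data):
    return sf.standardized_molecules(fixture_data)


@pytest.fixture(scope="session")
def fixture_matrix(fixture_mols, fixture_data):
    """Hologram matrix (default FS5-style config) + aligned labels."""
    config = hg.HologramConfig()
    X, ids, failures = hg.hologram_matrix(fixture_mols, config)
    assert not failures
    y = np.array([fixture_data.labels[i] for i in ids])
    return config, X, ids, y


@pytest.fixture(scope="session")
def fixture_split(fixture_matrix):
    _, X, ids, y = fixture_matrix
    idx = np.arange(len(ids))
    train_idx, test_idx = train_test_split(idx, train_size=0.7, random_state=17, stratify=y)
    return train_idx, test_idx


@pytest.fixture(scope="session")
def trained_model(fixture_matrix, fixture_split):
    _, X, ids, y = fixture_matrix
    train_idx, _ = fixture_split
    data = plsda.LabeledSet(X=X[train_idx], y=y[train_idx], ids=[ids[i] for i in train_idx])
    return plsda.fit_plsda(data, seed=17)


@pytest.fixture(scope="session")
def descriptor_table(default_spec, fixture_data):
    return sf.generate_descriptor_table(default_spec, fixture_data)
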