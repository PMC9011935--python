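import numpy as np
import pytest
from rdkit import RDLogger

from molclust.featurization import featurize_atoms, featurize_bonds, parse_smiles
from molclust.synthetic_data import MixtureSpec, fixture_smiles, gaussian_mixture

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def smiles_fixture():
    """60 generated drug-like molecules including the degenerate trio."""
    return fixture_smiles(60, seed=7)


@pytest.fixture(scope="session")
def parsed_molecules(smiles_fixture):
    return [parse_smiles(s, mol_id) for mol_id, s in smiles_fixture]


@pytest.fixture(scope="session")
def featurized(parsed_molecules):
    return [
        (m, featurize_atoms(m), featurize_bonds(m)) for m in parsed_molecules
    ]


@pytest.fixture(scope="session")
def six_blob_mixture():
    """Well-separated 6-cluster mixture for recovery tests."""
    spec = MixtureSpec(n=900, dim=16, k_true=6, separation=5, seed=11)
    return gaussian_mixture(spec)


@pytest.fixture(scope="session")
def rank2_table():
    """A rank-2 feature table (plus tiny noise): compressible by construction."""
    rng = np.random.default_rng(42)
    latent = rng.standard_normal((500, 2))
    loadings = rng.standard_normal((2, 40))
    return latent @ loadings + 0.01 * rng.standard_normal((500, 40))
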