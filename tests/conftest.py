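import numpy as np
import pytest

from pharmscreen import fixtures
from pharmscreen.core import Molecule
from pharmscreen.fixtures import FixtureSpec, _embed_smiles


def embed(smiles: str, name: str = "mol", seed: int = 7) -> Molecule:
    """A deterministic single-conformer 3D molecule from SMILES."""
    return Molecule.from_rdkit(_embed_smiles(smiles, name, seed), name=name)


@pytest.fixture(scope="session")
def template():
    return fixtures.make_template_ligand(7)


@pytest.fixture(scope="session")
def planted():
    """A small planted library: 4 actives (noisy template copies), 12 decoys."""
    spec = FixtureSpec(n_decoys=12, n_planted=4, geometric_noise=0.05, seed=3)
    return fixtures.make_planted_library(spec)


@pytest.fixture(scope="session")
def toy():
    return fixtures.make_toy_complex(0)


@pytest.fixture(scope="session")
def toy_pdb_path(toy, tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "complex.pdb"
    path.write_text(toy.pdb_text)
    return str(path)
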