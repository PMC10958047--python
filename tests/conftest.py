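import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from tsnap.blocks import BuildingBlock, enumerate_library
from tsnap.conformers import Conformer, ConformerEnsemble
from tsnap.fixtures import FixtureSpec, toy_building_blocks


@pytest.fixture(scope="session")
def toy_blocks_small():
    """1 thf x 2 enoates x 3 sidechains."""
    return toy_building_blocks(FixtureSpec(n_thf=1, n_enoate=2, n_side=3))


@pytest.fixture(scope="session")
def toy_manifest_small(toy_blocks_small):
    """24-compound library: 4 complete candidate groups of 6."""
    return enumerate_library(toy_blocks_small)


@pytest.fixture
def methane():
    mol = Chem.AddHs(Chem.MolFromSmiles("C"))
    AllChem.EmbedMolecule(mol, randomSeed=1)
    return mol


def random_ensemble(mol, n_confs, rng, energy_scale=5.0, coord_scale=1.0):
    """Synthetic ensemble: random coordinates and energies on a real topology."""
    n = mol.GetNumAtoms()
    confs = [
        Conformer(rng.normal(0.0, coord_scale, (n, 3)),
                  float(rng.normal(0.0, energy_scale)), iteration=i)
        for i in range(n_confs)
    ]
    return ConformerEnsemble(mol, confs)


@pytest.fixture
def rigid_polar_mol():
    """Small rigid tetrahydrofuran carrying donor/acceptor features."""
    return Chem.MolFromSmiles("OCC1CCC(C=O)O1")
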