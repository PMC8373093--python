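import numpy as np
import pytest
from rdkit import Chem

from npdesign import compounds
from npdesign.chem import parse_structure
from npdesign.fixtures import FixtureSpec, generate_blocks, generate_reference_library
from npdesign.reactions import builtin_registry


@pytest.fixture(scope="session")
def registry():
    return {s.id: s for s in builtin_registry()}


@pytest.fixture(scope="session")
def template():
    return compounds.mol("marinopyrrole_a")


@pytest.fixture(scope="session")
def designs():
    return {name: compounds.mol(name) for name in ["2", "2a", "2b", "3", "4"]}


@pytest.fixture(scope="session")
def small_library():
    """24-block seeded fixture library including the worked-route reagents."""
    return generate_blocks(FixtureSpec(seed=1, n_building_blocks=24))


@pytest.fixture(scope="session")
def reference_library():
    """5 planted target classes x 40 compounds at full separation."""
    return generate_reference_library(
        FixtureSpec(seed=2, compounds_per_target=40, separation=2.0)
    )


#: small, structurally varied molecules used by oracle and property tests
FIXTURE_SMILES = [
    "CCO",                      # ethanol
    "CC(=O)O",                  # acetic acid
    "OCC(=O)O",                 # glycolic acid
    "c1ccccc1",                 # benzene
    "Oc1ccccc1",                # phenol
    "c1ccncc1",                 # pyridine
    "c1cc[nH]c1",               # pyrrole
    "CCN",                      # ethylamine
    "CC(C)CC",                  # isopentane
    "O=Cc1ccccc1",              # benzaldehyde
    "Clc1ccccc1",               # chlorobenzene
    "CSC",                      # dimethyl sulfide
    "OCC(O)CO",                 # glycerol
    "C1CCCCC1",                 # cyclohexane
    "Cc1ccc(O)cc1",             # p-cresol
    "NC(=N)N",                  # guanidine
    "CC(=O)Oc1ccccc1",          # phenyl acetate
    "O=C(c1ccccc1)C(=O)c1ccccc1",  # benzil
    "[NH3+]CC([O-])=O",         # glycine zwitterion
    "C",                        # methane
]


@pytest.fixture(scope="session")
def fixture_mols():
    return [parse_structure(s) for s in FIXTURE_SMILES]


def permute_atoms(mol: Chem.Mol, seed: int) -> Chem.Mol:
    """Seeded random renumbering of a molecule's atoms."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(mol.GetNumAtoms()).tolist()
    return Chem.RenumberAtoms(mol, [int(i) for i in order])
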