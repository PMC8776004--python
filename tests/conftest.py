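import pytest
from rdkit import Chem

import simscreen as ss

LOSARTAN = "CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1"
OLMESARTAN = "CCCc1nc(C(C)(C)O)c(C(=O)O)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1"


@pytest.fixture(scope="session")
def sartans():
    """Prepared records for the two angiotensin-receptor blockers used as
    the worked similarity example."""
    kept, rejected = ss.prepare_library(
        [("losartan", LOSARTAN), ("olmesartan", OLMESARTAN)]
    )
    assert not rejected
    return {rec.id: rec for rec in kept}


@pytest.fixture(scope="session")
def random_smiles():
    """100 synthetic molecules for invariance sweeps (seeded)."""
    spec = ss.SyntheticLibrarySpec(n_molecules=100, seed=1234)
    return ss.generate_library(spec)


@pytest.fixture(scope="session")
def small_library_records():
    spec = ss.SyntheticLibrarySpec(n_molecules=50, seed=99)
    smiles = ss.generate_library(spec)
    kept, _ = ss.prepare_library([(f"L{i:03d}", s) for i, s in enumerate(smiles)])
    return kept


def shuffled_smiles(smiles: str, seed: int) -> str:
    """Rewrite a SMILES with its atoms in a different (seeded) order."""
    import random

    mol = Chem.MolFromSmiles(smiles)
    order = list(range(mol.GetNumAtoms()))
    random.Random(seed).shuffle(order)
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
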