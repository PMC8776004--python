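"""Murcko and generic-Murcko scaffold extraction and canonical keys.

The Murcko scaffold is the ring systems of a molecule plus the linkers
connecting them, with side chains pruned; the classical convention retains
atoms double-bonded directly to the scaffold (e.g. a ring carbonyl oxygen).
The generic scaffold additionally replaces every heavy atom by carbon and
every bond by a single bond, so benzene and cyclohexane collapse to the
same key.  Keys are canonical SMILES; scaffold screening matches on the
key, with the scaffold's ECFP4 fingerprint available as a prefilter index.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .fingerprints2d import BitFingerprint, ecfp_fingerprint
from .molprep import MoleculeRecord


@dataclass(frozen=True)
class ScaffoldKey:
    kind: str  # "murcko" | "generic"
    key: str  # canonical SMILES of the scaffold
    fingerprint: BitFingerprint | None = None

    def __post_init__(self):
        if self.kind not in ("murcko", "generic"):
            raise ValueError(f"unknown scaffold kind: {self.kind}")


def _as_mol(rec: MoleculeRecord | Chem.Mol) -> Chem.Mol:
    return rec.mol if isinstance(rec, MoleculeRecord) else rec


def murcko_scaffold(rec: MoleculeRecord | Chem.Mol) -> Chem.Mol | None:
    """Prune side chains down to ring systems + linkers.

    Returns ``None`` for acyclic molecules (no ring system, no scaffold).
    """
    mol = _as_mol(rec)
    if mol.GetRingInfo().NumRings() == 0:
        return None
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return scaffold


def generic_scaffold(rec: MoleculeRecord | Chem.Mol) -> Chem.Mol | None:
    """Murcko scaffold with all atoms -> C and all bonds -> single."""
    scaffold = murcko_scaffold(rec)
    if scaffold is None:
        return None
    generic = Chem.RWMol(scaffold)
    for atom in generic.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetIsAromatic(False)
        atom.SetFormalCharge(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
    for bond in generic.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    out = generic.GetMol()
    Chem.SanitizeMol(out)
    return out


def scaffold_key(
    rec: MoleculeRecord | Chem.Mol,
    kind: str = "murcko",
    with_fingerprint: bool = True,
) -> ScaffoldKey | None:
    """Canonical scaffold key (+ ECFP4 prefilter fingerprint).

    Identity is always decided on the canonical SMILES key; the fingerprint
    only serves as a fast prefilter and can collide under folding.
    """
    scaffold = murcko_scaffold(rec) if kind == "murcko" else generic_scaffold(rec)
    if kind not in ("murcko", "generic"):
        raise ValueError(f"unknown scaffold kind: {kind}")
    if scaffold is None:
        return None
    fp = ecfp_fingerprint(scaffold) if with_fingerprint else None
    return ScaffoldKey(kind=kind, key=Chem.MolToSmiles(scaffold), fingerprint=fp)
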