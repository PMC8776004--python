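"""Molecule standardization, filtering and conformer generation.

The library-preparation pipeline mirrors common virtual-screening practice:

1. parse (SMILES or SDF V2000),
2. keep the largest fragment (salt/solvate stripping),
3. filter: >= 6 heavy atoms, MW <= 1500 g/mol, elements restricted to
   H, C, N, O, S, P, B, F, Cl, Br, I in the largest fragment,
4. standardize: neutralize charges where a valence-legal neutral form
   exists, normalize aromaticity perception, drop explicit hydrogens,
   optionally canonicalize the tautomer,
5. de-duplicate on the canonical SMILES of the standardized structure.

3D methods additionally need conformer ensembles; :func:`generate_conformers`
embeds with ETKDG, ranks by MMFF94 (UFF fallback) energy, and attaches
Gasteiger partial charges and Wildman-Crippen atomic logP contributions,
which the 5-dimensional shape descriptor consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import EmbeddingError, MoleculeParseError

RDLogger.DisableLog("rdApp.*")

ALLOWED_ELEMENTS = frozenset(
    ["H", "C", "N", "O", "S", "P", "B", "F", "Cl", "Br", "I"]
)
MIN_HEAVY_ATOMS = 6
MAX_MOLECULAR_WEIGHT = 1500.0
DEFAULT_CONFORMER_SEED = 42


@dataclass
class MoleculeRecord:
    """A parsed molecule plus provenance flags.

    ``flags`` records which processing steps touched the record
    (``dialect:smiles``, ``largest_fragment``, ``neutralized``,
    ``non_neutralizable``, ``tautomer_canonicalized`` ...).
    """

    id: str
    mol: Chem.Mol
    source_smiles: str
    flags: set[str] = field(default_factory=set)

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def heavy_atom_count(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def molecular_weight(self) -> float:
        return Descriptors.MolWt(self.mol)


@dataclass
class ConformerSet:
    """Low-energy conformers with per-atom charges/lipophilicity.

    ``coordinates`` is a list of (n_atoms, 3) arrays in Angstrom;
    ``charges`` are Gasteiger partial charges in units of e and
    ``lipo`` the Wildman-Crippen atomic logP contributions (unitless).
    Atom order matches the hydrogen-explicit molecule in ``mol``.
    """

    record_id: str
    mol: Chem.Mol
    coordinates: list[np.ndarray]
    energies: list[float]
    charges: np.ndarray
    lipo: np.ndarray
    generation_seed: int

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class RejectedRecord:
    id: str
    source_text: str
    reasons: list[str]


def parse_input(text: str, record_id: str | None = None) -> MoleculeRecord:
    """Parse one SMILES line or one SDF (V2000) block into a record.

    A SMILES line may carry a whitespace-separated identifier after the
    structure.  SDF blocks are detected by the ``V2000`` counts line or the
    ``$$$$`` terminator.

    Raises
    ------
    MoleculeParseError
        if the text is empty or no molecule can be parsed from it.
    """
    if not text or not text.strip():
        raise MoleculeParseError(text, "empty input")

    stripped = text.strip()
    is_sdf = "V2000" in text or stripped.endswith("$$$$") or "\n" in stripped
    if is_sdf and "V2000" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=True)
        if mol is None:
            raise MoleculeParseError(text, "unparsable SDF block")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        rec_id = record_id or name or "mol"
        rec = MoleculeRecord(
            id=rec_id, mol=mol, source_smiles=Chem.MolToSmiles(mol)
        )
        rec.flags.add("dialect:sdf")
        return rec

    parts = stripped.split(None, 1)
    smiles = parts[0]
    inline_id = parts[1].strip() if len(parts) > 1 else None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(text, "unparsable SMILES")
    rec = MoleculeRecord(
        id=record_id or inline_id or smiles, mol=mol, source_smiles=smiles
    )
    rec.flags.add("dialect:smiles")
    return rec


def largest_fragment(rec: MoleculeRecord) -> MoleculeRecord:
    """Keep the connected component with the most heavy atoms.

    Ties break by larger molecular weight, then by lexicographically
    smallest canonical SMILES, so the choice is reproducible.
    """
    frags = Chem.GetMolFrags(rec.mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return rec
    ranked = sorted(
        frags,
        key=lambda m: (
            -m.GetNumHeavyAtoms(),
            -Descriptors.MolWt(m),
            Chem.MolToSmiles(m),
        ),
    )
    out = MoleculeRecord(
        id=rec.id,
        mol=ranked[0],
        source_smiles=rec.source_smiles,
        flags=set(rec.flags),
    )
    out.flags.add("largest_fragment")
    return out


def passes_filters(
    rec: MoleculeRecord,
    min_heavy: int = MIN_HEAVY_ATOMS,
    max_mw: float = MAX_MOLECULAR_WEIGHT,
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS,
) -> tuple[bool, list[str]]:
    """Check the heavy-atom / MW / element filters; both bounds inclusive.

    Returns ``(ok, reasons)`` where ``reasons`` lists every violated rule:
    ``too_few_heavy_atoms``, ``mw_too_high``, ``disallowed_element``.
    """
    reasons = []
    if rec.heavy_atom_count < min_heavy:
        reasons.append("too_few_heavy_atoms")
    if rec.molecular_weight > max_mw:
        reasons.append("mw_too_high")
    elements = {atom.GetSymbol() for atom in rec.mol.GetAtoms()}
    if not elements <= allowed_elements:
        reasons.append("disallowed_element")
    return (not reasons, reasons)


_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(
    rec: MoleculeRecord, canonicalize_tautomer: bool = False
) -> MoleculeRecord:
    """Neutralize, normalize aromaticity, make hydrogens implicit.

    Charges with a valence-legal neutral form are neutralized; groups with
    no such form (quaternary ammonium, ...) keep their charge and the record
    is flagged ``non_neutralizable``.  The optional tautomer pass uses the
    toolkit's canonical-tautomer algorithm and is off by default so query
    structures are respected as drawn.  Idempotent.
    """
    mol = Chem.RemoveHs(rec.mol)
    had_charges = any(a.GetFormalCharge() != 0 for a in mol.GetAtoms())
    mol = _UNCHARGER.uncharge(mol)
    flags = set(rec.flags)
    if had_charges:
        still_charged = any(a.GetFormalCharge() != 0 for a in mol.GetAtoms())
        flags.add("non_neutralizable" if still_charged else "neutralized")
    if canonicalize_tautomer:
        enumerator = rdMolStandardize.TautomerEnumerator()
        mol = enumerator.Canonicalize(mol)
        flags.add("tautomer_canonicalized")
    Chem.SanitizeMol(mol)
    flags.add("standardized")
    return MoleculeRecord(
        id=rec.id, mol=mol, source_smiles=rec.source_smiles, flags=flags
    )


def prepare_library(
    inputs: list[str] | list[tuple[str, str]],
    min_heavy: int = MIN_HEAVY_ATOMS,
    max_mw: float = MAX_MOLECULAR_WEIGHT,
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS,
    canonicalize_tautomers: bool = False,
) -> tuple[list[MoleculeRecord], list[RejectedRecord]]:
    """Run the full preparation pipeline over raw inputs.

    ``inputs`` is a list of SMILES/SDF texts or ``(id, text)`` pairs.
    Every input ends up in exactly one of the two output lists; duplicates
    (identical canonical SMILES after standardization) are resolved
    first-seen-wins.
    """
    kept: list[MoleculeRecord] = []
    rejected: list[RejectedRecord] = []
    seen: set[str] = set()
    for i, item in enumerate(inputs):
        if isinstance(item, tuple):
            rec_id, text = item
        else:
            rec_id, text = None, item
        try:
            rec = parse_input(text, record_id=rec_id)
        except MoleculeParseError:
            rejected.append(
                RejectedRecord(rec_id or f"input_{i}", str(item), ["parse_error"])
            )
            continue
        rec = largest_fragment(rec)
        ok, reasons = passes_filters(rec, min_heavy, max_mw, allowed_elements)
        if not ok:
            rejected.append(RejectedRecord(rec.id, rec.source_smiles, reasons))
            continue
        rec = standardize(rec, canonicalize_tautomer=canonicalize_tautomers)
        key = rec.canonical_smiles
        if key in seen:
            rejected.append(RejectedRecord(rec.id, rec.source_smiles, ["duplicate"]))
            continue
        seen.add(key)
        kept.append(rec)
    return kept, rejected


def generate_conformers(
    rec: MoleculeRecord,
    n_max: int,
    seed: int = DEFAULT_CONFORMER_SEED,
    pre_conformer_hook=None,
    n_pool: int | None = None,
) -> ConformerSet:
    """Embed up to ``n_max`` lowest-energy conformers (ETKDG, seeded).

    Shape-and-charge 3D descriptors use up to 20 conformers; the 3D circular
    fingerprint uses the top 3, matching the published protocols.  A pool of
    ``n_pool`` embeddings (default ``max(2 * n_max, 60)``) is generated,
    optimized and ranked by MMFF94 energy (UFF when MMFF parameters are
    missing), and the ``n_max`` lowest-energy distinct geometries are kept.
    The deep default pool makes the selected low-energy set nearly
    independent of the embedding seed.

    ``pre_conformer_hook`` is an optional ``Mol -> Mol`` callback applied
    before embedding — the slot where e.g. a protonation model would plug in;
    default is identity.

    Raises
    ------
    EmbeddingError
        when 3D embedding fails for the molecule.
    """
    mol = Chem.Mol(rec.mol)
    if pre_conformer_hook is not None:
        mol = pre_conformer_hook(mol)
    mol = Chem.AddHs(mol)
    if n_pool is None:
        n_pool = max(2 * n_max, 60)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.pruneRmsThresh = 0.35
    try:
        conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_pool, params=params)
    except (ValueError, RuntimeError) as exc:
        raise EmbeddingError(
            f"3D embedding failed for record {rec.id!r}: {exc}"
        ) from exc
    if len(conf_ids) == 0:
        raise EmbeddingError(f"3D embedding failed for record {rec.id!r}")

    energies = {}
    if AllChem.MMFFHasAllMoleculeParams(mol):
        props = AllChem.MMFFGetMoleculeProperties(mol)
        for cid in conf_ids:
            ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
            if ff is not None:
                ff.Minimize(maxIts=500)
                energies[cid] = ff.CalcEnergy()
    if not energies:
        for cid in conf_ids:
            ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
            ff.Minimize(maxIts=500)
            energies[cid] = ff.CalcEnergy()

    ranked = sorted(energies, key=lambda cid: (energies[cid], cid))[:n_max]

    AllChem.ComputeGasteigerCharges(mol)
    charges = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()], dtype=float
    )
    charges = np.nan_to_num(charges, nan=0.0, posinf=0.0, neginf=0.0)
    lipo = np.array([c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)])

    coords = [np.array(mol.GetConformer(cid).GetPositions()) for cid in ranked]
    return ConformerSet(
        record_id=rec.id,
        mol=mol,
        coordinates=coords,
        energies=[energies[cid] for cid in ranked],
        charges=charges,
        lipo=lipo,
        generation_seed=seed,
    )
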