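"""Synthetic chemical libraries and planted bioactivity tables.

Real calibration data (bioactivity databases with millions of compound-
target pairs) cannot ship with a library; this module generates desk-scale
stand-ins with known ground truth instead:

* :func:`generate_library` composes valence-legal molecules from a weighted
  fragment grammar, optionally in analog families so pairwise similarities
  cover the whole [0, 1] range the way congeneric series do in real
  screening decks.
* :func:`plant_activities` builds a (compound_id, target_id) table in which
  the probability that two compounds share a target is controlled by a
  monotone link on their 2D-fingerprint similarity — the statistical
  structure that threshold calibration assumes, with known parameters.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import GrammarError, SamplingError
from .fingerprints2d import BitFingerprint, ecfp_fingerprint

DEFAULT_FRAGMENT_GRAMMAR: dict[str, float] = {
    "c1ccccc1": 3.0,
    "c1ccncc1": 2.0,
    "c1ccc2ccccc2c1": 1.0,
    "c1ccsc1": 1.0,
    "c1ccoc1": 1.0,
    "C1CCCCC1": 2.0,
    "C1CCNCC1": 1.5,
    "C1CCOC1": 1.0,
    "CC": 2.0,
    "CCC": 1.5,
    "CCO": 1.5,
    "CN": 1.5,
    "CCN": 1.0,
    "C(=O)N": 1.5,
    "C(=O)O": 1.5,
    "C(F)(F)F": 1.0,
    "CCl": 1.0,
    "CBr": 0.5,
    "CS": 0.5,
    "C=C": 1.0,
}


@dataclass
class SyntheticLibrarySpec:
    n_molecules: int
    fragment_grammar: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAGMENT_GRAMMAR)
    )
    seed: int = 0
    min_fragments: int = 2
    max_fragments: int = 6
    #: molecules per analog family; 1 = independent random molecules
    family_size: int = 1


@dataclass
class PlantedActivityModel:
    """Ground-truth model linking fingerprint similarity to target sharing.

    ``similarity_link`` maps a Tanimoto similarity in [0, 1] to a
    probability of shared activity.  Two constructions are available:

    ``target_mode="pair"`` (default): each positive draw creates a minimal
    two-compound activity group (the lower-index compound is the group's
    anchor), so P(two compounds share a target) equals the link evaluated
    at their mutual ECFP4 similarity *exactly* — sharing cannot propagate
    transitively through a third compound.  This is the mode to use when a
    downstream analysis must see the planted link undistorted.

    ``target_mode="anchor"``: ``n_targets`` anchor compounds with distinct
    scaffolds each seed one target and every molecule joins with
    probability ``link(T(molecule, anchor))``.  More database-like, but
    cluster members share targets transitively, so the induced pairwise
    probability no longer equals the link.

    In both modes every compound additionally joins each of
    ``n_background_targets`` broad targets with probability ``base_rate``
    (similarity-independent noise) and orphans receive a private target.
    """

    similarity_link: Callable[[float], float]
    target_mode: str = "pair"
    n_targets: int | None = None
    base_rate: float = 0.0
    n_background_targets: int = 20
    seed: int = 0


def step_link(threshold: float, low: float = 0.0, high: float = 1.0):
    """Monotone step: ``low`` below ``threshold``, ``high`` at or above."""

    def link(s: float) -> float:
        return high if s >= threshold else low

    return link


def _attachment_atom(mol: Chem.Mol, offset: int = 0) -> int | None:
    """Lowest-index H-bearing atom (C/N preferred) at or after ``offset``."""
    for wanted in ((6, 7), None):
        for atom in mol.GetAtoms():
            if atom.GetIdx() < offset:
                continue
            if atom.GetTotalNumHs() > 0 and (
                wanted is None or atom.GetAtomicNum() in wanted
            ):
                return atom.GetIdx()
    return None


def _compose(fragments: list[str]) -> str | None:
    """Join fragments into a linear chain with single bonds.

    Attachment points are chosen deterministically (lowest-index H-bearing
    atom of the last-added fragment), so a fragment sequence maps to exactly
    one molecule and single-fragment edits yield close analogs.
    """
    mol = Chem.MolFromSmiles(fragments[0])
    if mol is None:
        return None
    last_offset = 0
    for smi in fragments[1:]:
        frag = Chem.MolFromSmiles(smi)
        if frag is None:
            return None
        a = _attachment_atom(mol, last_offset)
        if a is None:
            a = _attachment_atom(mol, 0)
        b = _attachment_atom(frag, 0)
        if a is None or b is None:
            return None
        n_before = mol.GetNumAtoms()
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        combined.AddBond(a, n_before + b, Chem.BondType.SINGLE)
        try:
            out = combined.GetMol()
            Chem.SanitizeMol(out)
        except Exception:
            return None
        mol = out
        last_offset = n_before
    return Chem.MolToSmiles(mol)


def generate_library(spec: SyntheticLibrarySpec) -> list[str]:
    """Generate ``n_molecules`` unique canonical SMILES from the grammar.

    With ``family_size > 1`` the library is organized in analog families
    emulating congeneric series: a base fragment sequence is drawn per
    family and each member applies a small edit (replace one fragment,
    replace two, or append one), so within-family pairwise similarities
    cover a broad range while cross-family pairs stay dissimilar.

    Raises
    ------
    GrammarError
        if the grammar cannot reach 6 heavy atoms or is empty.
    """
    if not spec.fragment_grammar:
        raise GrammarError("empty fragment grammar")
    frags = sorted(spec.fragment_grammar)
    weights = np.array([spec.fragment_grammar[f] for f in frags], float)
    weights = weights / weights.sum()
    frag_heavy = {}
    for f in frags:
        m = Chem.MolFromSmiles(f)
        if m is None:
            raise GrammarError(f"unparsable grammar fragment: {f}")
        frag_heavy[f] = m.GetNumHeavyAtoms()
    if max(frag_heavy.values()) * spec.max_fragments < 6:
        raise GrammarError("grammar cannot reach 6 heavy atoms")
    if spec.n_molecules == 0:
        return []

    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    seen: set[str] = set()

    def draw_sequence() -> list[str]:
        n_frag = int(rng.integers(spec.min_fragments, spec.max_fragments + 1))
        seq = [frags[i] for i in rng.choice(len(frags), size=n_frag, p=weights)]
        # pad until the sequence can reach 6 heavy atoms
        while sum(frag_heavy[f] for f in seq) < 6:
            seq.append(frags[int(rng.choice(len(frags), p=weights))])
        return seq

    def random_frag() -> str:
        return frags[int(rng.choice(len(frags), p=weights))]

    # family state: a fixed base sequence plus two designated variable
    # positions, emulating R-group enumeration around a constant core
    base_seq: list[str] | None = None
    var_positions: tuple[int, int] | None = None
    in_family = 0

    def family_variant() -> list[str]:
        seq = list(base_seq)
        p0, p1 = var_positions
        seq[p0] = random_frag()
        if rng.random() < 0.5:
            seq[p1] = random_frag()
        return seq

    max_attempts = 200 * max(spec.n_molecules, 1)
    attempts = 0
    while len(out) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        if spec.family_size > 1:
            if base_seq is None or in_family >= spec.family_size:
                base_seq = draw_sequence()
                pos = rng.choice(len(base_seq), size=min(2, len(base_seq)),
                                 replace=False)
                var_positions = (int(pos[0]), int(pos[-1]))
                in_family = 0
            seq = base_seq if in_family == 0 else family_variant()
        else:
            seq = draw_sequence()
        smi = _compose(seq)
        ok = smi is not None and smi not in seen
        if ok:
            m = Chem.MolFromSmiles(smi)
            ok = m is not None and m.GetNumHeavyAtoms() >= 6
        if not ok:
            if spec.family_size > 1 and in_family == 0:
                base_seq = None  # unusable family base: redraw
            continue
        seen.add(smi)
        out.append(smi)
        in_family += 1
    if len(out) < spec.n_molecules:
        raise GrammarError(
            f"could not generate {spec.n_molecules} unique molecules "
            f"({len(out)} after {attempts} attempts)"
        )
    return out


def tanimoto_similarity_matrix(fps: list[BitFingerprint]) -> np.ndarray:
    """Dense all-pairs Tanimoto matrix via packed-bit popcounts."""
    n = len(fps)
    length = fps[0].length_bits
    dense = np.zeros((n, length), dtype=np.uint8)
    for i, fp in enumerate(fps):
        if fp.on_bits:
            dense[i, sorted(fp.on_bits)] = 1
    packed = np.packbits(dense, axis=1)
    pops = np.bitwise_count(packed).sum(axis=1).astype(np.int32)
    sims = np.zeros((n, n), dtype=np.float32)
    block = 128
    for start in range(0, n, block):
        stop = min(start + block, n)
        inter = np.bitwise_count(
            packed[start:stop, None, :] & packed[None, :, :]
        ).sum(axis=2)
        union = pops[start:stop, None] + pops[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(union > 0, inter / union, 0.0)
        sims[start:stop] = s
    np.fill_diagonal(sims, 1.0)
    return sims


def compound_ids(n: int) -> list[str]:
    return [f"M{i:06d}" for i in range(n)]


def plant_activities(
    library: list[str],
    model: PlantedActivityModel,
    similarity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign library compounds to protein targets with similarity-linked
    probabilities; returns a (compound_id, target_id) table.

    See :class:`PlantedActivityModel` for the two constructions.
    ``similarity`` may carry a precomputed all-pairs ECFP4 Tanimoto matrix
    to avoid refingerprinting.

    Raises
    ------
    SamplingError
        if ``n_targets`` exceeds the library size.
    """
    if not library:
        raise SamplingError("empty library")
    n = len(library)
    if model.n_targets is not None and model.n_targets > n:
        raise SamplingError("n_targets exceeds library size")
    rng = np.random.default_rng(model.seed)
    ids = compound_ids(n)

    if similarity is None:
        fps = [ecfp_fingerprint(Chem.MolFromSmiles(s)) for s in library]
        similarity = tanimoto_similarity_matrix(fps)

    rows: list[tuple[str, str]] = []
    if model.target_mode == "pair":
        iu, ju = np.triu_indices(n, k=1)
        probs = np.array(
            [model.similarity_link(float(s)) for s in similarity[iu, ju]]
        )
        hits = rng.random(len(probs)) < probs
        for t_idx, (a, b) in enumerate(zip(iu[hits], ju[hits])):
            target = f"T{t_idx:06d}"
            rows.append((ids[a], target))
            rows.append((ids[b], target))
    elif model.target_mode == "anchor":
        n_targets = model.n_targets if model.n_targets is not None else n
        anchors = _distinct_scaffold_anchors(library, n_targets)
        for t_idx, anchor in enumerate(anchors):
            target = f"T{t_idx:06d}"
            probs = np.array(
                [model.similarity_link(float(s)) for s in similarity[anchor]]
            )
            probs[anchor] = 1.0  # the anchor defines its target
            draws = rng.random(n) < probs
            for m in np.nonzero(draws)[0]:
                rows.append((ids[m], target))
    else:
        raise ValueError(f"unknown target_mode: {model.target_mode}")

    if model.base_rate > 0 and model.n_background_targets > 0:
        joins = rng.random((n, model.n_background_targets)) < model.base_rate
        for m, t in zip(*np.nonzero(joins)):
            rows.append((ids[m], f"B{t:04d}"))

    covered = {c for c, _ in rows}
    for m, cid in enumerate(ids):
        if cid not in covered:
            rows.append((cid, f"P{m:06d}"))

    return pd.DataFrame(rows, columns=["compound_id", "target_id"])


def _distinct_scaffold_anchors(library: list[str], n_targets: int) -> list[int]:
    """Greedy pick of anchors with pairwise-distinct generic scaffolds,
    topping up with arbitrary compounds if scaffolds run out."""
    from .scaffolds import scaffold_key

    chosen: list[int] = []
    seen_keys: set[str] = set()
    for i, smi in enumerate(library):
        key = scaffold_key(Chem.MolFromSmiles(smi), "generic", with_fingerprint=False)
        label = key.key if key is not None else f"acyclic_{i}"
        if label not in seen_keys:
            seen_keys.add(label)
            chosen.append(i)
        if len(chosen) == n_targets:
            return chosen
    for i in range(len(library)):
        if i not in chosen:
            chosen.append(i)
        if len(chosen) == n_targets:
            break
    return chosen
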