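"""3D descriptors over conformer ensembles.

* :func:`es5d_vector` — ElectroShape-style 5-dimensional shape descriptor:
  atoms embedded at ``(x, y, z, charge_scale*q, lipo_scale*logP)``, six
  reference points, three distance moments each -> an 18-component vector.
* :func:`e3fp_fingerprint` — 3D circular fingerprint: iterative
  spherical-shell identifiers with connectivity and relative-orientation
  information, so stereoisomers separate at higher levels.

Both are invariant to rigid rotation/translation of the conformer; the
shape descriptor's cross-product references and the shell orientation signs
flip under mirror reflection, which is what distinguishes enantiomers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .errors import EmbeddingError
from .fingerprints2d import BitFingerprint, _initial_invariant
from .hashing import hash_ints
from .molprep import ConformerSet

# Å per elementary charge, from the ElectroShape line of methods
DEFAULT_CHARGE_SCALE = 25.0
DEFAULT_LIPO_SCALE = 25.0

E3FP_DEFAULT_LEVEL = 5
E3FP_DEFAULT_RADIUS_MULTIPLIER = 1.718
E3FP_DEFAULT_LENGTH = 1024
E3FP_CONFORMERS = 3
ES5D_MAX_CONFORMERS = 20


@dataclass(frozen=True)
class ES5DVector:
    """18 reals: (mean, stdev, cbrt-skewness) of atom distances to each of
    six reference points in the 5D embedding."""

    components: tuple[float, ...]

    def __post_init__(self):
        if len(self.components) != 18:
            raise ValueError("ES5D vector must have 18 components")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.components)


def _moments(dists: np.ndarray) -> tuple[float, float, float]:
    mean = float(dists.mean())
    centered = dists - mean
    std = float(np.sqrt((centered**2).mean()))
    m3 = float((centered**3).mean())
    return mean, std, float(np.cbrt(m3))


def es5d_vector(
    coords: np.ndarray,
    charges: np.ndarray,
    lipo: np.ndarray,
    charge_scale: float = DEFAULT_CHARGE_SCALE,
    lipo_scale: float = DEFAULT_LIPO_SCALE,
) -> ES5DVector:
    """5D shape-charge-lipophilicity descriptor of one conformer.

    Reference points: (1) the 5D centroid c1; (2) the atom farthest from c1;
    (3) the atom farthest from c2; (4, 5) points displaced from c1 along the
    normalized cross product of the spatial parts of c2-c1 and c3-c1 by
    half |c2-c1|, with the charge coordinate set to the extreme +/- scaled
    charge; (6) the analogous point with the lipophilicity coordinate at its
    extreme.  For each reference the mean, standard deviation and signed
    cube root of the third central moment of the atom distances are taken.

    Raises
    ------
    EmbeddingError
        for conformers with fewer than 2 atoms (references undefined).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise EmbeddingError("ES5D needs at least 2 atoms")
    X = np.column_stack(
        [coords, charge_scale * np.asarray(charges), lipo_scale * np.asarray(lipo)]
    )
    c1 = X.mean(axis=0)
    d1 = np.linalg.norm(X - c1, axis=1)
    c2 = X[int(d1.argmax())]
    d2 = np.linalg.norm(X - c2, axis=1)
    c3 = X[int(d2.argmax())]

    a3 = (c2 - c1)[:3]
    b3 = (c3 - c1)[:3]
    cr = np.cross(a3, b3)
    nrm = np.linalg.norm(cr)
    unit = cr / nrm if nrm > 1e-12 else np.zeros(3)
    spatial = c1[:3] + 0.5 * np.linalg.norm(a3) * unit

    q_axis = X[:, 3]
    l_axis = X[:, 4]
    c4 = np.concatenate([spatial, [q_axis.max()], [c1[4]]])
    c5 = np.concatenate([spatial, [q_axis.min()], [c1[4]]])
    c6 = np.concatenate([spatial, [c1[3]], [l_axis.max()]])

    components: list[float] = []
    for ref in (c1, c2, c3, c4, c5, c6):
        components.extend(_moments(np.linalg.norm(X - ref, axis=1)))
    return ES5DVector(tuple(components))


def es5d_vectors(conf_set: ConformerSet, **kwargs) -> list[ES5DVector]:
    """ES5D vector for every conformer in the set."""
    return [
        es5d_vector(c, conf_set.charges, conf_set.lipo, **kwargs)
        for c in conf_set.coordinates
    ]


# ---------------------------------------------------------------------------
# 3D circular fingerprint

_ORIENT_TOL = 1e-4


def e3fp_identifiers(
    mol: Chem.Mol,
    coords: np.ndarray,
    level: int = E3FP_DEFAULT_LEVEL,
    radius_multiplier: float = E3FP_DEFAULT_RADIUS_MULTIPLIER,
) -> set[int]:
    """Unfolded identifiers of the spherical-shell procedure.

    Hydrogens are skipped; shells at level ``t`` cover atoms within
    ``t * radius_multiplier`` Å of the center.  Each shell hashes the
    center's previous identifier with the sorted
    ``(neighbor-identifier, bonded-flag, orientation-sign)`` tuples of its
    member atoms.  The orientation sign is the sign of the projection of a
    member's direction onto the normal of the plane spanned by the first two
    sorted members, so mirror images hash differently from level 2 on.
    Shells covering an atom set already covered at an earlier level (or by a
    smaller identifier) are dropped.
    """
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    pos = {i: np.asarray(coords[i], dtype=float) for i in heavy}
    bonded = {
        i: {
            b.GetOtherAtomIdx(i)
            for b in mol.GetAtomWithIdx(i).GetBonds()
            if b.GetOtherAtom(mol.GetAtomWithIdx(i)).GetAtomicNum() > 1
        }
        for i in heavy
    }
    ids = {i: _initial_invariant(mol.GetAtomWithIdx(i)) for i in heavy}
    covered = {i: frozenset([i]) for i in heavy}

    features: list[tuple[int, int, frozenset[int]]] = [
        (0, ids[i], covered[i]) for i in heavy
    ]
    dists = {
        (i, j): float(np.linalg.norm(pos[i] - pos[j]))
        for i in heavy
        for j in heavy
        if i < j
    }

    def dist(i, j):
        return dists[(i, j)] if i < j else dists[(j, i)]

    for t in range(1, level + 1):
        r = t * radius_multiplier
        new_ids = {}
        new_cov = {}
        for c in heavy:
            members = [j for j in heavy if j != c and dist(c, j) <= r]
            entries = sorted(
                (ids[j], 1 if j in bonded[c] else 0, j) for j in members
            )
            # orientation signs relative to the first two sorted members
            signs = {j: 0 for j in members}
            if len(entries) >= 3:
                v1 = pos[entries[0][2]] - pos[c]
                v2 = pos[entries[1][2]] - pos[c]
                normal = np.cross(v1, v2)
                nn = np.linalg.norm(normal)
                if nn > _ORIENT_TOL:
                    normal /= nn
                    for j in members:
                        proj = float(np.dot(pos[j] - pos[c], normal))
                        if abs(proj) > _ORIENT_TOL:
                            signs[j] = 1 if proj > 0 else -1
            payload = [t, ids[c]]
            for ident, bflag, j in entries:
                payload.extend((ident, bflag, signs[j]))
            new_ids[c] = hash_ints(payload)
            cov = set(covered[c])
            for j in members:
                cov |= covered[j]
            new_cov[c] = frozenset(cov)
        ids, covered = new_ids, new_cov
        features.extend((t, ids[i], covered[i]) for i in heavy)

    best: dict[frozenset[int], tuple[int, int]] = {}
    for it, ident, aset in features:
        prev = best.get(aset)
        if prev is None or (it, ident) < prev:
            best[aset] = (it, ident)
    return {ident for _, ident in best.values()}


def e3fp_fingerprint(
    mol: Chem.Mol,
    coords: np.ndarray,
    level: int = E3FP_DEFAULT_LEVEL,
    radius_multiplier: float = E3FP_DEFAULT_RADIUS_MULTIPLIER,
    length: int = E3FP_DEFAULT_LENGTH,
) -> BitFingerprint:
    """Folded 3D circular fingerprint of one conformer."""
    ids = e3fp_identifiers(mol, coords, level, radius_multiplier)
    return BitFingerprint(length, frozenset(i % length for i in ids))


def e3fp_fingerprints(conf_set: ConformerSet, **kwargs) -> list[BitFingerprint]:
    """One fingerprint per conformer in the set."""
    return [e3fp_fingerprint(conf_set.mol, c, **kwargs) for c in conf_set.coordinates]
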