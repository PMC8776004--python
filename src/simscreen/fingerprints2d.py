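"""The five 2D fingerprint methods, implemented from their algorithmic
definitions.

* :func:`fp2_fingerprint` — path-based fingerprint: every linear atom path of
  1-7 atoms, canonical traversal direction, hashed to one bit.
* :func:`ecfp_fingerprint` — extended-connectivity (Morgan) fingerprint with
  diameter 4 by default.
* :func:`mhfp_signature` — MinHash fingerprint over circular-substructure
  SMILES shingles (radius 3 = up to 6 bonds, "MHFP6").
* :func:`pharm2d_fingerprint` — 2-point and 3-point pharmacophore
  fingerprint with binned topological distances.
* :func:`erg_fingerprint` — extended reduced-graph fingerprint with fuzzy
  incrementation.

Only the molecular graph is taken from the chemistry toolkit; the
fingerprint mathematics (path/shell enumeration, hashing, MinHash,
reduced-graph construction) is implemented here.  Hashing is FNV-1a, 32-bit,
pinned in :mod:`simscreen.hashing`: a different dialect would produce
different folded bits, so it is frozen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .features import FeaturePoint, assign_features
from .hashing import hash_ints, hash_str
from .molprep import MoleculeRecord

# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class BitFingerprint:
    """Fixed-length binary fingerprint stored as its set-bit indices."""

    length_bits: int
    on_bits: frozenset[int]

    def __post_init__(self):
        if any(b < 0 or b >= self.length_bits for b in self.on_bits):
            raise ValueError("on_bits outside [0, length_bits)")

    @property
    def popcount(self) -> int:
        return len(self.on_bits)

    def to_hex(self) -> str:
        """Hex encoding, most-significant bit of the vector first."""
        n = 0
        for b in self.on_bits:
            n |= 1 << b
        return format(n, f"0{self.length_bits // 4}x")

    @classmethod
    def from_hex(cls, hexstr: str, length_bits: int) -> "BitFingerprint":
        n = int(hexstr, 16)
        bits = frozenset(i for i in range(length_bits) if n >> i & 1)
        return cls(length_bits, bits)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.length_bits, dtype=np.uint8)
        arr[sorted(self.on_bits)] = 1
        return arr


@dataclass(frozen=True)
class MinHashSignature:
    """MinHash signature: per-permutation minima of hashed shingles."""

    k: int
    seed: int
    minima: tuple[int, ...]

    def __post_init__(self):
        if len(self.minima) != self.k:
            raise ValueError("signature length != k")


@dataclass
class ErGVector:
    """Sparse reduced-graph pharmacophore-pair vector.

    Keys are ``(prop_i, prop_j, distance)`` with ``prop_i <= prop_j``
    lexicographically; values are non-negative reals (fuzzy counts).
    """

    max_distance: int
    entries: dict[tuple[str, str, int], float] = field(default_factory=dict)

    def norm_sq(self) -> float:
        return sum(v * v for v in self.entries.values())


def _as_mol(rec: MoleculeRecord | Chem.Mol) -> Chem.Mol:
    return rec.mol if isinstance(rec, MoleculeRecord) else rec


def _canonical_order(mol: Chem.Mol) -> Chem.Mol:
    """Copy of the molecule with atoms in canonical-rank order.

    Used by encoders whose intermediate choices (rooted fragment SMILES,
    reduced-graph node numbering) depend on atom indices: renumbering makes
    those choices a function of the structure alone, so the fingerprints are
    invariant under input atom reordering.
    """
    ranks = list(Chem.CanonicalRankAtoms(mol))
    perm = sorted(range(mol.GetNumAtoms()), key=lambda i: ranks[i])
    return Chem.RenumberAtoms(mol, perm)


# ---------------------------------------------------------------------------
# FP2-style path fingerprint

_BOND_TOKEN = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 5,
}

MAX_PATH_ATOMS = 7
# single-atom paths of these elements carry no information (FP2 convention)
_EXCLUDED_SINGLE_ATOMS = {6, 7, 8}


def enumerate_path_fragments(mol: Chem.Mol, max_atoms: int = MAX_PATH_ATOMS):
    """Distinct path fragments of 1..max_atoms atoms, as token tuples.

    The dialect follows the classical path-based (FP2) convention: atoms
    contribute their atomic number only, bonds their order with aromatic
    bonds as 5.  A linear fragment is the canonical (lexicographically
    smaller) direction of its ``(atom, bond, atom, ...)`` token sequence,
    prefixed with 0; a ring-closure fragment is the canonical
    rotation/reflection of its cyclic ``(bond, atom)`` sequence, prefixed
    with 1.  Single-atom C/N/O fragments are skipped.  The result is the
    *set* of distinct fragments (two occurrences of the same substructure
    set the same bit).
    """
    tokens = [a.GetAtomicNum() for a in mol.GetAtoms()]
    bond_tok = {}
    adjacency: list[list[int]] = [[] for _ in range(mol.GetNumAtoms())]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        t = _BOND_TOKEN.get(bond.GetBondType(), 1)
        bond_tok[(i, j)] = bond_tok[(j, i)] = t
        adjacency[i].append(j)
        adjacency[j].append(i)

    fragments: set[tuple[int, ...]] = set()

    def linear_tokens(path: tuple[int, ...]) -> tuple[int, ...]:
        seq = []
        for n, idx in enumerate(path):
            if n:
                seq.append(bond_tok[(path[n - 1], idx)])
            seq.append(tokens[idx])
        rev = seq[::-1]
        return (0,) + tuple(min(seq, rev))

    def ring_tokens(path: tuple[int, ...]) -> tuple[int, ...]:
        n = len(path)
        # (incoming-bond, atom) pairs around the cycle; incoming bond of the
        # first atom is the ring-closure bond
        pairs = [
            (
                bond_tok[(path[k - 1], path[k])] if k else bond_tok[(path[-1], path[0])],
                tokens[path[k]],
            )
            for k in range(n)
        ]
        best = None
        for direction in (pairs, [(pairs[(k + 1) % n][0], pairs[k][1]) for k in range(n)][::-1]):
            for rot in range(n):
                cand = tuple(
                    x for k in range(n) for x in direction[(rot + k) % n]
                )
                if best is None or cand < best:
                    best = cand
        return (1,) + best

    for start in range(mol.GetNumAtoms()):
        atom = mol.GetAtomWithIdx(start)
        if atom.GetAtomicNum() not in _EXCLUDED_SINGLE_ATOMS:
            fragments.add(linear_tokens((start,)))
        stack = [(start, (start,))]
        while stack:
            current, path = stack.pop()
            if len(path) == max_atoms:
                continue
            for nbr in adjacency[current]:
                if nbr == start and len(path) >= 3:
                    fragments.add(ring_tokens(path))
                    continue
                if nbr in path:
                    continue
                new_path = path + (nbr,)
                fragments.add(linear_tokens(new_path))
                stack.append((nbr, new_path))
    return fragments


def fp2_fingerprint(
    rec: MoleculeRecord | Chem.Mol, length: int = 2048
) -> BitFingerprint:
    """Path-based fingerprint: linear paths of 1-7 atoms plus ring
    closures, each distinct fragment hashed to one bit."""
    mol = _as_mol(rec)
    bits = {hash_ints(seq) % length for seq in enumerate_path_fragments(mol)}
    return BitFingerprint(length, frozenset(bits))


# ---------------------------------------------------------------------------
# extended-connectivity (Morgan) fingerprint


def _initial_invariant(atom: Chem.Atom) -> int:
    return hash_ints(
        (
            atom.GetAtomicNum(),
            atom.GetDegree(),  # heavy-atom neighbours
            atom.GetTotalValence() - atom.GetTotalNumHs(),
            atom.GetTotalNumHs(),
            atom.GetFormalCharge(),
            1 if atom.IsInRing() else 0,
        )
    )


def ecfp_identifiers(
    rec: MoleculeRecord | Chem.Mol, diameter: int = 4
) -> set[int]:
    """Unfolded 32-bit substructure identifiers of the ECFP procedure.

    Runs ``diameter/2`` update rounds; bond tokens use the same dialect as
    the path fingerprint (aromatic = 5).  Duplicate identifiers covering an
    identical substructure (same atom and bond sets) are removed — the
    earlier iteration wins, then the smaller identifier.
    """
    mol = _as_mol(rec)
    n_rounds = diameter // 2
    ids = [_initial_invariant(a) for a in mol.GetAtoms()]
    # covered substructure per atom: (atom set, bond set); radius-0 shells
    # cover the atom itself and no bonds
    atom_sets = [frozenset([i]) for i in range(mol.GetNumAtoms())]
    bond_sets: list[frozenset[int]] = [frozenset() for _ in mol.GetAtoms()]
    neighbors: list[list[tuple[int, int, int]]] = []  # (bond_token, nbr, bond_idx)
    for atom in mol.GetAtoms():
        entry = []
        for bond in atom.GetBonds():
            nbr = bond.GetOtherAtomIdx(atom.GetIdx())
            entry.append((_BOND_TOKEN.get(bond.GetBondType(), 1), nbr, bond.GetIdx()))
        neighbors.append(entry)

    # (iteration, identifier, covered substructure) for every atom/round
    features = [
        (0, ids[i], (atom_sets[i], bond_sets[i])) for i in range(len(ids))
    ]
    for it in range(1, n_rounds + 1):
        new_ids = []
        new_asets = []
        new_bsets = []
        for i in range(len(ids)):
            env = sorted((t, ids[j]) for t, j, _ in neighbors[i])
            payload = [it, ids[i]]
            for t, nid in env:
                payload.extend((t, nid))
            new_ids.append(hash_ints(payload))
            a_cov = set(atom_sets[i])
            b_cov = set(bond_sets[i])
            for _, j, bidx in neighbors[i]:
                b_cov.add(bidx)
                a_cov |= atom_sets[j]
                b_cov |= bond_sets[j]
            new_asets.append(frozenset(a_cov))
            new_bsets.append(frozenset(b_cov))
        ids, atom_sets, bond_sets = new_ids, new_asets, new_bsets
        features.extend(
            (it, ids[i], (atom_sets[i], bond_sets[i])) for i in range(len(ids))
        )

    best: dict[tuple, tuple[int, int]] = {}
    for it, ident, substruct in features:
        prev = best.get(substruct)
        if prev is None or (it, ident) < prev:
            best[substruct] = (it, ident)
    return {ident for _, ident in best.values()}


def ecfp_fingerprint(
    rec: MoleculeRecord | Chem.Mol, diameter: int = 4, length: int = 2048
) -> BitFingerprint:
    """Extended-connectivity fingerprint folded modulo ``length``."""
    ids = ecfp_identifiers(rec, diameter)
    return BitFingerprint(length, frozenset(i % length for i in ids))


# ---------------------------------------------------------------------------
# MinHash fingerprint (MHFP)

_MINHASH_PRIME = 2147483647  # 2^31 - 1
_GLOBAL_MINHASH_SEED = 42


def _minhash_coefficients(k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    a = rng.integers(1, _MINHASH_PRIME, size=k, dtype=np.uint64)
    b = rng.integers(0, _MINHASH_PRIME, size=k, dtype=np.uint64)
    return a, b


def mhfp_shingles(rec: MoleculeRecord | Chem.Mol, radius: int = 3) -> set[str]:
    """Circular-substructure SMILES shingles for radii 1..radius.

    Each shingle is the SMILES of the substructure within ``r`` bonds of a
    central atom, rooted at that atom; shingling runs on the canonically
    renumbered molecule so the set is independent of input atom order.
    """
    mol = _canonical_order(_as_mol(rec))
    shingles: set[str] = set()
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        for r in range(1, radius + 1):
            env = Chem.FindAtomEnvironmentOfRadiusN(mol, r, idx)
            if not env:
                continue
            atoms = set()
            for bidx in env:
                bond = mol.GetBondWithIdx(bidx)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            smiles = Chem.MolFragmentToSmiles(
                mol,
                atomsToUse=sorted(atoms),
                bondsToUse=list(env),
                rootedAtAtom=idx,
                canonical=True,
            )
            shingles.add(smiles)
    return shingles


def minhash_from_shingles(
    shingles: set[str], k: int = 2048, seed: int = _GLOBAL_MINHASH_SEED
) -> MinHashSignature:
    """MinHash a shingle set with k universal-hash permutations
    ``(a*x + b) mod p``, p = 2^31 - 1, over FNV-hashed shingles."""
    a, b = _minhash_coefficients(k, seed)
    if not shingles:
        return MinHashSignature(k, seed, tuple([_MINHASH_PRIME] * k))
    x = np.array([hash_str(s) for s in sorted(shingles)], dtype=np.uint64)
    # (k, n) matrix of permuted hashes; uint64 holds a*x < 2^62 exactly
    hashed = (a[:, None] * x[None, :] + b[:, None]) % _MINHASH_PRIME
    return MinHashSignature(k, seed, tuple(int(v) for v in hashed.min(axis=1)))


def mhfp_signature(
    rec: MoleculeRecord | Chem.Mol,
    radius: int = 3,
    k: int = 2048,
    seed: int = _GLOBAL_MINHASH_SEED,
) -> MinHashSignature:
    """MHFP6 signature (radius 3 = circular substructures up to 6 bonds)."""
    return minhash_from_shingles(mhfp_shingles(rec, radius), k, seed)


# ---------------------------------------------------------------------------
# 2D pharmacophore fingerprint

# bin edges for topological distances; bin i covers [edge_i, edge_{i+1})
DEFAULT_DISTANCE_BINS = (1, 2, 3, 4, 5, 6, 7, 8)  # last bin is 8+


def _bin_distance(d: int, edges: tuple[int, ...]) -> int:
    for i in range(len(edges) - 1):
        if edges[i] <= d < edges[i + 1]:
            return i
    return len(edges) - 1


def _feature_distances(mol: Chem.Mol, points: list[FeaturePoint]) -> np.ndarray:
    dmat = Chem.GetDistanceMatrix(mol)
    n = len(points)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = min(
                int(dmat[a][b])
                for a in points[i].atoms
                for b in points[j].atoms
            )
            out[i][j] = out[j][i] = d
    return out


def _canonical_triangle(
    kinds: tuple[str, str, str], bins: tuple[int, int, int]
) -> tuple:
    """Lexicographically smallest labelled form of a feature triangle.

    ``bins`` are the binned distances (d01, d02, d12); all 6 vertex
    permutations are considered.
    """
    best = None
    dist = {(0, 1): bins[0], (0, 2): bins[1], (1, 2): bins[2]}
    for perm in itertools.permutations(range(3)):
        ks = tuple(kinds[p] for p in perm)
        def d(a, b):
            key = (min(perm[a], perm[b]), max(perm[a], perm[b]))
            return dist[key]
        cand = (ks, (d(0, 1), d(0, 2), d(1, 2)))
        if best is None or cand < best:
            best = cand
    return best


def pharm2d_fingerprint(
    rec: MoleculeRecord | Chem.Mol,
    length: int = 2048,
    bin_edges: tuple[int, ...] = DEFAULT_DISTANCE_BINS,
) -> BitFingerprint:
    """2-point and 3-point pharmacophore fingerprint.

    Every pair and triangle of feature points is encoded as a canonical
    token (sorted feature classes + binned topological distances) and hashed
    to a bit.  Pairs at distance 0 (overlapping points) are skipped.
    """
    mol = _as_mol(rec)
    points = assign_features(mol)
    if len(points) < 2:
        return BitFingerprint(length, frozenset())
    dists = _feature_distances(mol, points)
    bits: set[int] = set()
    for i, j in itertools.combinations(range(len(points)), 2):
        if dists[i][j] < 1:
            continue
        ki, kj = sorted((points[i].kind, points[j].kind))
        token = f"P|{ki},{kj}|{_bin_distance(dists[i][j], bin_edges)}"
        bits.add(hash_str(token) % length)
    for i, j, k in itertools.combinations(range(len(points)), 3):
        if min(dists[i][j], dists[i][k], dists[j][k]) < 1:
            continue
        kinds = (points[i].kind, points[j].kind, points[k].kind)
        b = (
            _bin_distance(dists[i][j], bin_edges),
            _bin_distance(dists[i][k], bin_edges),
            _bin_distance(dists[j][k], bin_edges),
        )
        ks, ds = _canonical_triangle(kinds, b)
        token = f"T|{','.join(ks)}|{ds[0]},{ds[1]},{ds[2]}"
        bits.add(hash_str(token) % length)
    return BitFingerprint(length, frozenset(bits))


# ---------------------------------------------------------------------------
# extended reduced-graph (ErG) fingerprint

_ERG_PROPS = ("donor", "acceptor", "cation", "anion", "aromatic", "hydrophobic")


def _aromatic_ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Fused aromatic ring systems as atom-index sets."""
    ri = mol.GetRingInfo()
    aromatic_rings = [
        set(ring)
        for ring in ri.AtomRings()
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring)
    ]
    systems: list[set[int]] = []
    for ring in aromatic_rings:
        merged = ring
        keep = []
        for sys_ in systems:
            if sys_ & merged:
                merged |= sys_
            else:
                keep.append(sys_)
        keep.append(merged)
        systems = keep
    return systems


def build_reduced_graph(mol: Chem.Mol):
    """Collapse aromatic ring systems to centroid nodes.

    Returns ``(node_atoms, edges, node_props)`` where ``node_atoms`` maps
    node index -> original atom set, ``edges`` is a set of index pairs and
    ``node_props`` maps node index -> list of property labels.
    """
    systems = _aromatic_ring_systems(mol)
    atom_to_node: dict[int, int] = {}
    node_atoms: list[set[int]] = []
    for sys_ in systems:
        node = len(node_atoms)
        node_atoms.append(set(sys_))
        for a in sys_:
            atom_to_node[a] = node
    for atom in mol.GetAtoms():
        if atom.GetIdx() not in atom_to_node:
            node = len(node_atoms)
            node_atoms.append({atom.GetIdx()})
            atom_to_node[atom.GetIdx()] = node

    edges: set[tuple[int, int]] = set()
    for bond in mol.GetBonds():
        u = atom_to_node[bond.GetBeginAtomIdx()]
        v = atom_to_node[bond.GetEndAtomIdx()]
        if u != v:
            edges.add((min(u, v), max(u, v)))

    points = assign_features(mol)
    node_props: dict[int, list[str]] = {i: [] for i in range(len(node_atoms))}
    n_systems = len(systems)
    for node in range(n_systems):
        node_props[node].append("aromatic")
    for p in points:
        if p.kind == "aromatic":
            continue  # carried by centroid nodes above
        touched = sorted({atom_to_node[a] for a in p.atoms})
        # a feature fully inside a collapsed ring system attaches to its
        # centroid; otherwise to the first non-ring node it touches
        target = touched[0]
        for t in touched:
            if t >= n_systems:
                target = t
                break
        node_props[target].append(p.kind)
    return node_atoms, edges, node_props


def _reduced_graph_distances(n_nodes: int, edges: set[tuple[int, int]]) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    rows, cols = [], []
    for u, v in edges:
        rows.extend((u, v))
        cols.extend((v, u))
    mat = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    return shortest_path(mat, method="D", unweighted=True)


def erg_fingerprint(
    rec: MoleculeRecord | Chem.Mol,
    max_distance: int = 15,
    fuzz: float = 0.3,
) -> ErGVector:
    """Reduced-graph pharmacophore-pair vector with fuzzy incrementation.

    For each pair of property points at reduced-graph distance ``d`` within
    ``max_distance``, the ``(p_i, p_j, d)`` entry gains 1 and the entries at
    ``d±1`` (within [1, max_distance]) gain ``fuzz``.  The fuzzy increments
    make near-miss distances count, which favours scaffold hopping.
    """
    mol = _canonical_order(_as_mol(rec))
    node_atoms, edges, node_props = build_reduced_graph(mol)
    dmat = _reduced_graph_distances(len(node_atoms), edges)
    vec = ErGVector(max_distance=max_distance)
    carriers = [
        (node, prop) for node, props in node_props.items() for prop in props
    ]
    increments: dict[tuple[str, str, int], list[float]] = {}
    for (n1, p1), (n2, p2) in itertools.combinations(carriers, 2):
        if n1 == n2:
            continue
        d = dmat[n1][n2]
        if not np.isfinite(d):
            continue
        d = int(d)
        if d < 1 or d > max_distance:
            continue
        a, b = sorted((p1, p2))
        for dd, inc in ((d - 1, fuzz), (d, 1.0), (d + 1, fuzz)):
            if 1 <= dd <= max_distance and inc > 0:
                increments.setdefault((a, b, dd), []).append(inc)
    # summing in sorted order keeps the result independent of carrier order
    for key, vals in increments.items():
        vec.entries[key] = float(sum(sorted(vals)))
    return vec
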