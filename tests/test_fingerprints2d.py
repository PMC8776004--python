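import itertools

import numpy as np
import pytest
from rdkit import Chem

import simscreen as ss
from simscreen.errors import SignatureMismatchError
from simscreen.fingerprints2d import (
    ecfp_identifiers,
    enumerate_path_fragments,
    mhfp_shingles,
    minhash_from_shingles,
)
from simscreen.hashing import hash_ints

from conftest import shuffled_smiles


def brute_force_benzene_fragments():
    """Independent enumeration of path fragments in the aromatic 6-cycle.

    Every linear path of n atoms (2 <= n <= 6) has the same token sequence
    (all carbons, all aromatic bonds), and the only ring closure is the full
    6-cycle; single-atom carbon fragments are excluded.
    """
    frags = set()
    for n in range(2, 7):
        seq = [6]
        for _ in range(n - 1):
            seq.extend([5, 6])
        frags.add((0,) + tuple(seq))
    ring = [5, 6] * 6
    frags.add((1,) + tuple(ring))
    return frags


class TestFP2:
    def test_methane_is_empty(self):
        assert ss.fp2_fingerprint(Chem.MolFromSmiles("C")).popcount == 0

    def test_benzene_matches_bruteforce_oracle(self):
        oracle = brute_force_benzene_fragments()
        fp = ss.fp2_fingerprint(Chem.MolFromSmiles("c1ccccc1"))
        expected_bits = {hash_ints(f) % 2048 for f in oracle}
        assert fp.on_bits == frozenset(expected_bits)
        assert enumerate_path_fragments(Chem.MolFromSmiles("c1ccccc1")) == oracle

    def test_single_atom_exclusion_only_cno(self):
        # chlorine survives as a single-atom fragment, carbon does not
        assert ss.fp2_fingerprint(Chem.MolFromSmiles("[SiH3]Cl")).popcount >= 2

    def test_hexane_fragment_count(self):
        # linear C6: paths of 2..6 atoms, one distinct token sequence each
        frags = enumerate_path_fragments(Chem.MolFromSmiles("CCCCCC"))
        assert len(frags) == 5


class TestECFP:
    def test_ethanol_has_six_identifiers(self):
        # 3 atoms (radius 0) + 3 distinct radius-1 shells; both radius-2
        # shells duplicate the full-molecule substructure of the central
        # carbon's radius-1 shell
        assert len(ecfp_identifiers(Chem.MolFromSmiles("CCO"))) == 6

    def test_single_heavy_atom_one_identifier(self):
        assert len(ecfp_identifiers(Chem.MolFromSmiles("O"))) == 1

    def test_identifiers_fold_length_independent(self):
        mol = Chem.MolFromSmiles("CCOc1ccccc1")
        ids = ecfp_identifiers(mol)
        fp_1024 = ss.ecfp_fingerprint(mol, length=1024)
        fp_2048 = ss.ecfp_fingerprint(mol, length=2048)
        assert fp_1024.on_bits == frozenset(i % 1024 for i in ids)
        assert fp_2048.on_bits == frozenset(i % 2048 for i in ids)

    def test_diameter_zero_counts_atom_types(self):
        # propane: two distinct atom environments (CH3, CH2)
        assert len(ecfp_identifiers(Chem.MolFromSmiles("CCC"), diameter=0)) == 2


class TestMHFP:
    def test_identical_molecules_estimate_one(self):
        a = ss.mhfp_signature(Chem.MolFromSmiles("CCOc1ccccc1"))
        b = ss.mhfp_signature(Chem.MolFromSmiles("O(CC)c1ccccc1"))
        assert ss.minhash_similarity(a, b) == 1.0

    def test_known_jaccard_within_binomial_error(self):
        # two hand-built shingle sets with exact Jaccard 0.5
        A = {"a", "b", "c"}
        B = {"a", "b", "d"}
        sa = minhash_from_shingles(A, k=2048)
        sb = minhash_from_shingles(B, k=2048)
        est = ss.minhash_similarity(sa, sb)
        sigma = np.sqrt(0.5 * 0.5 / 2048)
        assert abs(est - 0.5) < 3 * sigma

    def test_methane_shingles_degenerate(self):
        assert len(mhfp_shingles(Chem.MolFromSmiles("C"), radius=3)) <= 3

    def test_estimator_mae_against_exact_oracle(self):
        # 100 random shingle-set pairs; MinHash estimate vs exact Jaccard
        rng = np.random.default_rng(5)
        errors = []
        for _ in range(100):
            universe = [f"s{i}" for i in range(rng.integers(20, 200))]
            a = {s for s in universe if rng.random() < 0.6}
            b = {s for s in universe if rng.random() < 0.6}
            if not a or not b:
                continue
            exact = len(a & b) / len(a | b)
            est = ss.minhash_similarity(
                minhash_from_shingles(a), minhash_from_shingles(b)
            )
            errors.append(abs(est - exact))
        assert np.mean(errors) < 0.02

    def test_mismatched_signatures_rejected(self):
        a = minhash_from_shingles({"x"}, k=512)
        b = minhash_from_shingles({"x"}, k=1024)
        with pytest.raises(SignatureMismatchError):
            ss.minhash_similarity(a, b)


class TestPharm2D:
    def test_ethane_no_features(self):
        assert ss.pharm2d_fingerprint(Chem.MolFromSmiles("CC")).popcount == 0

    def test_aminophenol_bits_match_manual_oracle(self):
        # 4-aminophenol: two donors (N, O) and one aromatic ring.
        # Hand-computed shortest paths: N-O = 5 (bin 4), N-ring = O-ring = 1
        # (bin 0); the two donor-aromatic pairs share one token.  Triangle
        # canonical form: (aromatic, donor, donor) with bins (0, 0, 4).
        from simscreen.hashing import hash_str

        expected = {
            hash_str("P|donor,donor|4") % 2048,
            hash_str("P|aromatic,donor|0") % 2048,
            hash_str("T|aromatic,donor,donor|0,0,4") % 2048,
        }
        fp = ss.pharm2d_fingerprint(Chem.MolFromSmiles("Nc1ccc(O)cc1"))
        assert fp.on_bits == frozenset(expected)

    def test_bit_indices_stable_across_runs(self):
        smi = "NCCc1ccc(O)cc1"
        a = ss.pharm2d_fingerprint(Chem.MolFromSmiles(smi))
        b = ss.pharm2d_fingerprint(Chem.MolFromSmiles(smi))
        assert a.on_bits == b.on_bits


class TestErG:
    def test_benzene_collapses_to_single_node(self):
        vec = ss.erg_fingerprint(Chem.MolFromSmiles("c1ccccc1"))
        assert vec.entries == {}

    def test_fuzzy_increment_rule(self):
        # 4-hydroxybutanal: hydroxyl donor and carbonyl acceptor at reduced
        # distance 4 -> 1.0 at d=4 and 0.3 at d=3, d=5
        vec = ss.erg_fingerprint(Chem.MolFromSmiles("OCCC=O"))
        assert vec.entries == pytest.approx(
            {
                ("acceptor", "donor", 4): 1.0,
                ("acceptor", "donor", 3): 0.3,
                ("acceptor", "donor", 5): 0.3,
            }
        )

    def test_zero_fuzz_gives_integer_entries(self):
        vec = ss.erg_fingerprint(Chem.MolFromSmiles("OCCC=O"), fuzz=0.0)
        assert all(float(v).is_integer() for v in vec.entries.values())

    def test_max_distance_respected(self):
        vec = ss.erg_fingerprint(Chem.MolFromSmiles("OCCCCCCCCCCCC=O"),
                                 max_distance=5)
        assert all(d <= 5 for _, _, d in vec.entries)


@pytest.mark.parametrize(
    "method",
    ["fp2", "ecfp4", "mhfp6", "pharm2d", "erg"],
)
def test_permutation_invariance(method, random_smiles):
    """All five 2D methods must be invariant under input atom reordering."""
    featurize = {
        "fp2": lambda m: ss.fp2_fingerprint(m).on_bits,
        "ecfp4": lambda m: ss.ecfp_fingerprint(m).on_bits,
        "mhfp6": lambda m: ss.mhfp_signature(m).minima,
        "pharm2d": lambda m: ss.pharm2d_fingerprint(m).on_bits,
        "erg": lambda m: ss.erg_fingerprint(m).entries,
    }[method]
    for smi in random_smiles[:20]:
        ref = featurize(Chem.MolFromSmiles(smi))
        for seed in range(3):
            shuffled = shuffled_smiles(smi, seed)
            assert featurize(Chem.MolFromSmiles(shuffled)) == ref, smi
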