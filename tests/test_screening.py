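import math

import pytest

import simscreen as ss
from simscreen.errors import StoreMismatchError
from simscreen.screening import CombinedModel, combined_score, featurize
from simscreen.store import FingerprintStore


@pytest.fixture(scope="module")
def ecfp4_store(small_library_records):
    entries = [
        (rec.id, ss.ecfp_fingerprint(rec)) for rec in small_library_records
    ]
    return FingerprintStore(method="ecfp4", params={"length": 2048},
                            entries=entries)


@pytest.fixture(scope="module")
def generic_store(small_library_records):
    entries = []
    for rec in small_library_records:
        key = ss.scaffold_key(rec, "generic", with_fingerprint=False)
        if key is not None:
            entries.append((rec.id, key.key))
    return FingerprintStore(method="generic", params={}, entries=entries)


class TestDefaultThresholds:
    def test_table_values(self):
        assert ss.DEFAULT_THRESHOLDS == {
            "mhfp6": 0.18,
            "e3fp": 0.2,
            "ecfp4": 0.25,
            "pharm2d": 0.35,
            "fp2": 0.48,
            "erg": 0.75,
            "es5d": 0.83,
        }

    def test_config_picks_method_default(self):
        cfg = ss.ScreeningConfig(method="fp2")
        assert cfg.threshold == 0.48


class TestScreen:
    def test_library_member_query_ranked_first(
        self, ecfp4_store, small_library_records
    ):
        query = small_library_records[7]
        hits = ss.screen(query, ecfp4_store, ss.ScreeningConfig(method="ecfp4"))
        assert hits[0].library_id == query.id
        assert hits[0].score == 1.0
        assert hits[0].rank == 1

    def test_unreachable_threshold_empty(self, ecfp4_store, small_library_records):
        cfg = ss.ScreeningConfig(method="ecfp4", threshold=1.01)
        assert ss.screen(small_library_records[0], ecfp4_store, cfg) == []

    def test_no_hit_below_default_threshold(
        self, ecfp4_store, small_library_records
    ):
        for query in small_library_records[:5]:
            hits = ss.screen(query, ecfp4_store, ss.ScreeningConfig(method="ecfp4"))
            assert all(h.score >= 0.25 for h in hits)

    def test_method_mismatch_rejected_before_scoring(
        self, ecfp4_store, small_library_records
    ):
        with pytest.raises(StoreMismatchError):
            ss.screen(
                small_library_records[0],
                ecfp4_store,
                ss.ScreeningConfig(method="fp2"),
            )

    def test_scores_match_pairwise_oracle(self, ecfp4_store, small_library_records):
        # screening the whole store must equal mapping the pairwise score
        query = small_library_records[3]
        cfg = ss.ScreeningConfig(method="ecfp4", threshold=0.0, max_hits=10_000)
        hits = {h.library_id: h.score for h in ss.screen(query, ecfp4_store, cfg)}
        qf = ss.ecfp_fingerprint(query)
        for lib_id, fp in ecfp4_store.entries:
            assert hits[lib_id] == pytest.approx(ss.tanimoto(qf, fp))

    def test_ranking_descending_with_id_tiebreak(
        self, ecfp4_store, small_library_records
    ):
        cfg = ss.ScreeningConfig(method="ecfp4", threshold=0.0, max_hits=10_000)
        hits = ss.screen(small_library_records[0], ecfp4_store, cfg)
        for a, b in zip(hits, hits[1:]):
            assert (a.score, b.library_id) >= (b.score, a.library_id)

    def test_3d_store_size_guard(self, small_library_records):
        store = FingerprintStore(method="es5d", params={}, entries=[("x", [])] * 10)
        cfg = ss.ScreeningConfig(method="es5d", store_limit_3d=5)
        with pytest.raises(StoreMismatchError):
            ss.screen(small_library_records[0], store, cfg)


class TestScaffoldScreen:
    def test_generic_match_across_ring_chemistry(self, generic_store):
        # toluene's generic scaffold is the plain 6-carbon ring, matching
        # any library member built on a single 6-ring
        query = ss.parse_input("Cc1ccccc1")
        hits = ss.scaffold_screen(query, generic_store, kind="generic")
        expected = {
            lib_id for lib_id, key in generic_store.entries if key == "C1CCCCC1"
        }
        assert {h.library_id for h in hits} == expected
        assert all(h.score is None for h in hits)

    def test_acyclic_query_warns_and_empty(self, generic_store):
        query = ss.parse_input("CCCCCCO")
        with pytest.warns(UserWarning):
            assert ss.scaffold_screen(query, generic_store, kind="generic") == []

    def test_kind_mismatch_rejected(self, generic_store):
        with pytest.raises(StoreMismatchError):
            ss.scaffold_screen(
                ss.parse_input("Cc1ccccc1"), generic_store, kind="murcko"
            )

    def test_fingerprint_collision_does_not_match(self):
        # identity is decided on the canonical key, never the fingerprint:
        # two entries with different keys stay distinct even if their
        # prefilter fingerprints collide
        store = FingerprintStore(
            method="generic", params={},
            entries=[("ring6", "C1CCCCC1"), ("ring5", "C1CCCC1")],
        )
        hits = ss.scaffold_screen(
            ss.parse_input("Cc1ccccc1"), store, kind="generic"
        )
        assert [h.library_id for h in hits] == ["ring6"]


class TestCombinedScore:
    def test_zero_model_gives_half(self):
        model = CombinedModel(0.0, 0.0, 0.0)
        assert combined_score(0.3, 0.9, model) == 0.5

    def test_balanced_logit_arithmetic(self):
        model = CombinedModel(-4.0, 2.0, 2.0)
        assert combined_score(1.0, 1.0, model) == 0.5

    def test_monotone_in_each_similarity(self):
        model = CombinedModel(-2.0, 3.0, 1.5)
        grid = [combined_score(s, 0.4, model) for s in (0.0, 0.3, 0.7, 1.0)]
        assert grid == sorted(grid)
        assert all(0.0 < p < 1.0 for p in grid)

    def test_matches_logistic_closed_form(self):
        model = CombinedModel(-1.0, 2.0, 0.5)
        z = -1.0 + 2.0 * 0.6 + 0.5 * 0.2
        assert combined_score(0.6, 0.2, model) == pytest.approx(
            1 / (1 + math.exp(-z))
        )


def test_featurize_unknown_method_rejected(small_library_records):
    with pytest.raises(ValueError):
        featurize(small_library_records[0], "nope")


def test_combined_screen_scores_are_probabilities(small_library_records):
    members = small_library_records[:3]
    fp2_store = FingerprintStore(
        method="fp2", params={"length": 2048},
        entries=[(r.id, ss.fp2_fingerprint(r)) for r in members],
    )
    es5d_store = FingerprintStore(
        method="es5d", params={"n_conformers": 2, "conformer_seed": 42},
        entries=[
            (r.id, ss.es5d_vectors(ss.generate_conformers(r, 2, seed=42)))
            for r in members
        ],
    )
    from simscreen.screening import combined_screen

    hits = combined_screen(
        members[0], fp2_store, es5d_store, ss.DEFAULT_COMBINED_MODEL,
        threshold=0.0,
    )
    assert len(hits) == 3
    assert all(0.0 < h.score < 1.0 for h in hits)
    assert hits[0].library_id == members[0].id  # self is the best hit
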