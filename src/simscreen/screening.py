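"""Similarity screening of a query molecule against a fingerprint store.

Each method has a calibrated default similarity threshold — the similarity
at which two compounds have a ~50% probability of sharing a protein target —
so hit lists from different methods are comparably enriched.  The combined
2D/3D method turns a path-fingerprint score and a 5D-shape score into that
probability directly, via logistic regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import EmptyInputError, StoreMismatchError
from .fingerprints2d import (
    ecfp_fingerprint,
    erg_fingerprint,
    fp2_fingerprint,
    mhfp_signature,
    pharm2d_fingerprint,
)
from .fingerprints3d import (
    E3FP_CONFORMERS,
    ES5D_MAX_CONFORMERS,
    e3fp_fingerprints,
    es5d_vectors,
)
from .molprep import MoleculeRecord, generate_conformers
from .scaffolds import scaffold_key
from .similarity import (
    algebraic_tanimoto,
    es5d_similarity,
    minhash_similarity,
    multi_conformer_similarity,
    tanimoto,
)

#: Calibrated per-method lower similarity limits (probability ≈ 0.5 of a
#: shared protein target).
DEFAULT_THRESHOLDS: dict[str, float] = {
    "mhfp6": 0.18,
    "e3fp": 0.2,
    "ecfp4": 0.25,
    "pharm2d": 0.35,
    "fp2": 0.48,
    "erg": 0.75,
    "es5d": 0.83,
}

METHODS_2D = ("fp2", "ecfp4", "mhfp6", "pharm2d", "erg")
METHODS_3D = ("es5d", "e3fp")
SCAFFOLD_KINDS = ("murcko", "generic")

#: 3D and combined methods refuse stores above this size unless forced
DEFAULT_3D_STORE_LIMIT = 100_000


@dataclass
class ScreeningConfig:
    method: str
    threshold: float | None = None  # None -> method default
    max_hits: int = 400
    aggregate: str = "max"  # multi-conformer aggregation
    force_large_store: bool = False
    store_limit_3d: int = DEFAULT_3D_STORE_LIMIT

    def __post_init__(self):
        if self.threshold is None:
            self.threshold = DEFAULT_THRESHOLDS.get(self.method, 0.0)
        # thresholds above 1 are allowed and simply unreachable
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class ScreenHit:
    library_id: str
    rank: int
    score: float | None = None  # None for scaffold searches
    method: str = ""


@dataclass
class CombinedModel:
    """Logistic model P(shared target) from FP2 and ES5D similarities."""

    intercept: float
    coef_fp2: float
    coef_es5d: float


#: Default combined-model coefficients, fitted once on this package's own
#: synthetic calibration set (80-molecule analog library, smooth
#: similarity-target link; see docs/methods.md).  They are NOT derived from
#: any published bioactivity dataset — supply your own model for real data.
DEFAULT_COMBINED_MODEL = CombinedModel(
    intercept=-2.926, coef_fp2=5.297, coef_es5d=2.659
)


def combined_score(s_fp2: float, s_es5d: float, model: CombinedModel) -> float:
    """logistic(β0 + β_FP2·s_fp2 + β_ES5D·s_es5d) in (0, 1)."""
    z = model.intercept + model.coef_fp2 * s_fp2 + model.coef_es5d * s_es5d
    return 1.0 / (1.0 + math.exp(-z))


def featurize(
    rec: MoleculeRecord,
    method: str,
    n_conformers: int | None = None,
    conformer_seed: int = 42,
    **params,
):
    """Compute the features of one record for a given method tag."""
    if method == "fp2":
        return fp2_fingerprint(rec, **params)
    if method == "ecfp4":
        return ecfp_fingerprint(rec, **params)
    if method == "mhfp6":
        return mhfp_signature(rec, **params)
    if method == "pharm2d":
        return pharm2d_fingerprint(rec, **params)
    if method == "erg":
        return erg_fingerprint(rec, **params)
    if method in METHODS_3D:
        n = n_conformers or (
            E3FP_CONFORMERS if method == "e3fp" else ES5D_MAX_CONFORMERS
        )
        confs = generate_conformers(rec, n_max=n, seed=conformer_seed)
        if method == "e3fp":
            return e3fp_fingerprints(confs, **params)
        return es5d_vectors(confs, **params)
    if method in SCAFFOLD_KINDS:
        return scaffold_key(rec, kind=method)
    raise ValueError(f"unknown method: {method}")


def pairwise_similarity(features_a, features_b, method: str, aggregate: str = "max"):
    """Dispatch the correct pairwise score for a method tag."""
    if method == "fp2" or method == "ecfp4" or method == "pharm2d":
        return tanimoto(features_a, features_b)
    if method == "mhfp6":
        return minhash_similarity(features_a, features_b)
    if method == "erg":
        return algebraic_tanimoto(features_a, features_b)
    if method == "es5d":
        return multi_conformer_similarity(
            features_a, features_b, es5d_similarity, aggregate
        )
    if method == "e3fp":
        return multi_conformer_similarity(
            features_a, features_b, tanimoto, aggregate
        )
    raise ValueError(f"no pairwise score for method: {method}")


def screen(query: MoleculeRecord, store, cfg: ScreeningConfig) -> list[ScreenHit]:
    """Rank store entries by similarity to the query.

    The query is fingerprinted once with the store's parameters, every
    entry is scored, scores below the configured threshold are dropped, and
    the rest are returned ranked (descending score, ties by id) up to
    ``max_hits``.

    Raises
    ------
    StoreMismatchError
        if the store was built with a different method, or a 3D/combined
        store exceeds the size guard without ``force_large_store``.
    """
    if store.method != cfg.method:
        raise StoreMismatchError(
            f"store method {store.method!r} != config method {cfg.method!r}"
        )
    if (
        cfg.method in METHODS_3D
        and len(store.entries) > cfg.store_limit_3d
        and not cfg.force_large_store
    ):
        raise StoreMismatchError(
            "3D screening disabled for very large stores; pass "
            "force_large_store=True to override"
        )
    qf = featurize(query, cfg.method, **store.featurize_params())
    scored = []
    for lib_id, payload in store.entries:
        s = pairwise_similarity(qf, payload, cfg.method, cfg.aggregate)
        if s >= cfg.threshold:
            scored.append((lib_id, s))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        ScreenHit(library_id=lib_id, rank=i + 1, score=s, method=cfg.method)
        for i, (lib_id, s) in enumerate(scored[: cfg.max_hits])
    ]


def scaffold_screen(
    query: MoleculeRecord, store, kind: str = "murcko", max_hits: int = 400
) -> list[ScreenHit]:
    """Return entries whose canonical scaffold key equals the query's.

    No similarity score is attached: by definition every returned scaffold
    is identical to the query's.  Acyclic queries (no scaffold) yield an
    empty result with a warning.
    """
    if store.method != kind:
        raise StoreMismatchError(
            f"store holds {store.method!r} keys, requested {kind!r}"
        )
    qkey = scaffold_key(query, kind=kind, with_fingerprint=False)
    if qkey is None:
        import warnings

        warnings.warn("acyclic query has no scaffold; empty result")
        return []
    hits = [
        lib_id for lib_id, key in store.entries if key == qkey.key
    ]
    hits.sort()
    return [
        ScreenHit(library_id=h, rank=i + 1, score=None, method=kind)
        for i, h in enumerate(hits[:max_hits])
    ]


def combined_screen(
    query: MoleculeRecord,
    fp2_store,
    es5d_store,
    model: CombinedModel,
    threshold: float = 0.5,
    max_hits: int = 400,
    conformer_seed: int = 42,
) -> list[ScreenHit]:
    """Combined 2D/3D screen: logistic probability from FP2 + ES5D scores."""
    ids_2d = dict(fp2_store.entries)
    ids_3d = dict(es5d_store.entries)
    common = sorted(set(ids_2d) & set(ids_3d))
    if not common:
        raise EmptyInputError("stores share no compound ids")
    qf2 = featurize(query, "fp2", **fp2_store.featurize_params())
    params3 = es5d_store.featurize_params()
    params3.setdefault("conformer_seed", conformer_seed)
    qf3 = featurize(query, "es5d", **params3)
    scored = []
    for lib_id in common:
        s2 = tanimoto(qf2, ids_2d[lib_id])
        s3 = multi_conformer_similarity(qf3, ids_3d[lib_id], es5d_similarity)
        p = combined_score(s2, s3, model)
        if p >= threshold:
            scored.append((lib_id, p))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        ScreenHit(library_id=lib_id, rank=i + 1, score=p, method="combined")
        for i, (lib_id, p) in enumerate(scored[:max_hits])
    ]
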