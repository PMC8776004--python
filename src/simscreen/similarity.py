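"""Pairwise similarity scores and multi-conformer aggregation.

All scores live in [0, 1]: 1 for identical encodings, approaching 0 for
unrelated molecules.  Note the documented 3D caveat: conformer ensembles
generated separately for a query and for its identical twin in a library
can differ, so 3D self-similarity may come out below 1.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import EmptyInputError, LengthMismatchError, SignatureMismatchError
from .fingerprints2d import BitFingerprint, ErGVector, MinHashSignature
from .fingerprints3d import ES5DVector


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto (Jaccard) coefficient |A∩B| / |A∪B| of two bit sets.

    Two empty fingerprints are defined as similarity 0 (with a warning)
    rather than NaN.
    """
    if a.length_bits != b.length_bits:
        raise LengthMismatchError(
            f"fingerprint lengths differ: {a.length_bits} vs {b.length_bits}"
        )
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0")
        return 0.0
    return len(a.on_bits & b.on_bits) / union


def minhash_similarity(a: MinHashSignature, b: MinHashSignature) -> float:
    """Fraction of matching minima: unbiased estimator of set Jaccard."""
    if a.k != b.k or a.seed != b.seed:
        raise SignatureMismatchError(
            "signatures built with different k or permutation seed"
        )
    eq = sum(1 for x, y in zip(a.minima, b.minima) if x == y)
    return eq / a.k


def algebraic_tanimoto(a: ErGVector, b: ErGVector) -> float:
    """Tanimoto in its algebraic form for real-valued sparse vectors:
    ``a·b / (|a|² + |b|² − a·b)``."""
    dot = sum(v * b.entries.get(k, 0.0) for k, v in a.entries.items())
    denom = a.norm_sq() + b.norm_sq() - dot
    if denom <= 0:
        warnings.warn("algebraic Tanimoto of two empty vectors defined as 0")
        return 0.0
    return dot / denom


def es5d_similarity(a: ES5DVector, b: ES5DVector) -> float:
    """Manhattan-distance-based score ``1 / (1 + mean |a_i − b_i|)``."""
    va, vb = a.as_array(), b.as_array()
    return 1.0 / (1.0 + float(np.abs(va - vb).mean()))


def multi_conformer_similarity(
    features_a: list,
    features_b: list,
    base,
    aggregate: str = "max",
) -> float:
    """Score two conformer ensembles: ``base`` over the full cross product,
    aggregated with max (best geometry pair, default) or mean."""
    if not features_a or not features_b:
        raise EmptyInputError("empty conformer feature list")
    scores = [base(fa, fb) for fa in features_a for fb in features_b]
    if aggregate == "max":
        return max(scores)
    if aggregate == "mean":
        return float(np.mean(scores))
    raise ValueError(f"unknown aggregation: {aggregate}")
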