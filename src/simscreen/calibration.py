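"""Similarity-threshold calibration.

The procedure estimates, per fingerprint method, the probability that two
compounds share a protein target as a function of their similarity: sample
pairs known to share a target and random background pairs from a bioactivity
table, bin their similarities, and estimate a per-bin probability with the
two classes reweighted to an effective 1:1 prior (the positive:random
sampling ratio is a design choice of the dataset, not a biological prior).
The similarity at which the — optionally isotonic-smoothed — curve first
reaches and stays above probability 0.5 becomes the method's screening
threshold.  The same pair dataset also fits the combined 2D/3D logistic
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression

from .errors import CalibrationError, SamplingError
from .screening import CombinedModel

DEFAULT_BIN_WIDTH = 0.02


@dataclass
class PairDataset:
    """Sampled compound pairs: positives share >= 1 target, randoms are
    uniform draws (which may share a target by chance, uncorrected)."""

    positive_pairs: list[tuple[str, str]]
    random_pairs: list[tuple[str, str]]
    seed: int

    @property
    def n_positive(self) -> int:
        return len(self.positive_pairs)

    @property
    def n_random(self) -> int:
        return len(self.random_pairs)


@dataclass
class ProbabilityCurve:
    """Binned similarity -> P(shared target), with per-bin counts."""

    bin_edges: np.ndarray
    positive_counts: np.ndarray
    random_counts: np.ndarray
    probability: np.ndarray  # NaN for empty bins
    smoothed: np.ndarray | None = None  # isotonic pass, NaN for empty bins
    method: str = ""
    weight: float = 1.0

    @property
    def occupied(self) -> np.ndarray:
        return (self.positive_counts + self.random_counts) > 0

    def estimates(self) -> np.ndarray:
        return self.smoothed if self.smoothed is not None else self.probability


def build_pair_dataset(
    activity: pd.DataFrame,
    n_pos: int,
    n_rand: int,
    seed: int,
) -> PairDataset:
    """Sample ``n_pos`` distinct shared-target pairs and ``n_rand`` uniform
    random pairs from a (compound_id, target_id) table.

    Raises
    ------
    SamplingError
        if fewer than ``n_pos`` distinct shared-target pairs exist.
    """
    if activity.empty:
        raise SamplingError("empty activity table")
    if n_pos < 1 or n_rand < 1:
        raise SamplingError("n_pos and n_rand must be >= 1")
    rng = np.random.default_rng(seed)

    shared: set[tuple[str, str]] = set()
    for _, group in activity.groupby("target_id"):
        members = sorted(set(group["compound_id"]))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                shared.add((members[i], members[j]))
    if len(shared) < n_pos:
        raise SamplingError(
            f"only {len(shared)} distinct shared-target pairs, need {n_pos}"
        )
    shared_list = sorted(shared)
    idx = rng.choice(len(shared_list), size=n_pos, replace=False)
    positives = [shared_list[i] for i in idx]

    compounds = sorted(set(activity["compound_id"]))
    n = len(compounds)
    if n < 2:
        raise SamplingError("need at least 2 distinct compounds")
    ii = rng.integers(0, n, size=n_rand)
    jj = rng.integers(0, n - 1, size=n_rand)
    jj = np.where(jj >= ii, jj + 1, jj)  # uniform j != i
    randoms = [
        (compounds[min(a, b)], compounds[max(a, b)]) for a, b in zip(ii, jj)
    ]
    return PairDataset(positive_pairs=positives, random_pairs=randoms, seed=seed)


def probability_curve(
    ds: PairDataset,
    sim_fn,
    bin_width: float = DEFAULT_BIN_WIDTH,
    prevalence_correction: float = 1.0,
    isotonic: bool = True,
    method: str = "",
) -> ProbabilityCurve:
    """Estimate P(shared target | similarity bin).

    Per occupied bin ``b``: ``P(b) = w·N_pos(b) / (w·N_pos(b) + N_rand(b))``
    with ``w = (n_rand / n_pos) · prevalence_correction`` — the default
    reweights the two samples to an effective 1:1 prior so the sampling
    ratio does not distort the probabilities.  The optional isotonic pass
    enforces a monotone curve (count-weighted).

    ``sim_fn(id_a, id_b) -> float`` supplies the similarity of a pair.
    """
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    pos_sims = np.array([sim_fn(a, b) for a, b in ds.positive_pairs])
    rand_sims = np.array([sim_fn(a, b) for a, b in ds.random_pairs])
    pos_counts, _ = np.histogram(pos_sims, bins=edges)
    rand_counts, _ = np.histogram(rand_sims, bins=edges)
    if pos_counts.sum() + rand_counts.sum() == 0:
        raise CalibrationError("all bins empty")

    w = (ds.n_random / ds.n_positive) * prevalence_correction
    total = w * pos_counts + rand_counts
    occupied = (pos_counts + rand_counts) > 0
    prob = np.full(len(pos_counts), np.nan)
    prob[occupied] = (w * pos_counts[occupied]) / total[occupied]

    smoothed = None
    if isotonic:
        centers = 0.5 * (edges[:-1] + edges[1:])
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(centers[occupied], prob[occupied], sample_weight=total[occupied])
        smoothed = np.full(len(pos_counts), np.nan)
        smoothed[occupied] = iso.predict(centers[occupied])

    return ProbabilityCurve(
        bin_edges=edges,
        positive_counts=pos_counts,
        random_counts=rand_counts,
        probability=prob,
        smoothed=smoothed,
        method=method,
        weight=w,
    )


def threshold_at(curve: ProbabilityCurve, p: float = 0.5) -> float:
    """Lower edge of the first occupied bin whose probability reaches ``p``
    and stays at or above ``p`` for every higher occupied bin.

    Raises
    ------
    CalibrationError
        if the curve never reaches ``p`` in that sustained sense.
    """
    est = curve.estimates()
    occupied = np.where(curve.occupied)[0]
    if len(occupied) == 0:
        raise CalibrationError("curve has no occupied bins")
    candidate = None
    for idx in occupied:
        if est[idx] >= p:
            if candidate is None:
                candidate = idx
        else:
            candidate = None
    if candidate is None:
        raise CalibrationError(f"curve never sustains probability >= {p}")
    return float(curve.bin_edges[candidate])


@dataclass
class CombinedFit:
    model: CombinedModel
    converged: bool
    separation_flagged: bool = False
    std_errors: np.ndarray = field(default_factory=lambda: np.zeros(3))


def fit_combined_logistic(
    s_fp2: np.ndarray,
    s_es5d: np.ndarray,
    labels: np.ndarray,
    prevalence_correction: float = 1.0,
    max_iter: int = 1000,
) -> CombinedFit:
    """Weighted maximum-likelihood logistic fit of shared-target labels on
    (FP2 similarity, ES5D similarity).

    Positives are reweighted by ``(n_random / n_positive) ·
    prevalence_correction`` as in :func:`probability_curve`.  Near-perfect
    separation (exploding coefficients under a near-unregularized fit) is
    flagged and refit with moderate L2 regularization.  Standard errors come
    from the inverse Fisher information at the fit.
    """
    X = np.column_stack([np.asarray(s_fp2, float), np.asarray(s_es5d, float)])
    y = np.asarray(labels, int)
    n_pos = int(y.sum())
    n_rand = int(len(y) - n_pos)
    if n_pos == 0 or n_rand == 0:
        raise CalibrationError("need both positive and random pairs to fit")
    w = np.where(y == 1, (n_rand / n_pos) * prevalence_correction, 1.0)

    def _fit(C):
        clf = LogisticRegression(C=C, max_iter=max_iter, solver="lbfgs")
        clf.fit(X, y, sample_weight=w)
        return clf

    clf = _fit(C=1e6)
    # near-unregularized coefficients beyond ~15 over a unit-range feature
    # indicate (quasi-)separation
    separation = bool(np.abs(clf.coef_).max() > 15)
    if separation:
        clf = _fit(C=1.0)

    beta = np.array([clf.intercept_[0], clf.coef_[0][0], clf.coef_[0][1]])
    Xd = np.column_stack([np.ones(len(y)), X])
    p = 1.0 / (1.0 + np.exp(-(Xd @ beta)))
    W = w * p * (1 - p)
    fisher = Xd.T @ (Xd * W[:, None])
    try:
        cov = np.linalg.inv(fisher)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)

    converged = bool(clf.n_iter_[0] < max_iter)
    return CombinedFit(
        model=CombinedModel(
            intercept=float(beta[0]),
            coef_fp2=float(beta[1]),
            coef_es5d=float(beta[2]),
        ),
        converged=converged,
        separation_flagged=separation,
        std_errors=se,
    )
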