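# Methods

`simscreen` implements a ligand-based virtual-screening stack: molecule
standardization, seven 2D/3D fingerprint methods, scaffold-identity search,
and the calibration procedure that converts raw similarity scores into
probability-of-shared-target thresholds. This note documents the models,
the numerical choices, and what the synthetic data do and do not show.

## Library preparation

Inputs (SMILES lines or SDF V2000 blocks) pass through five stages: parse →
largest fragment → filters → standardize → de-duplicate. The filters keep
molecules with at least 6 heavy atoms, molecular weight at most 1500 g/mol
(standard atomic weights, implicit hydrogens included), and largest-fragment
elements within {H, C, N, O, S, P, B, F, Cl, Br, I}; both bounds are
inclusive, and the MW filter is applied after largest-fragment selection,
consistent with the element rule's largest-fragment phrasing.
Standardization neutralizes charges wherever a valence-legal neutral form
exists (quaternary centers and fixed charges are kept and flagged), relies
on the toolkit's aromaticity perception as the single aromatic model, and
removes explicit hydrogens. Tautomer canonicalization is a hook, off by
default so a query structure is screened as drawn. Protonation-state
assignment is deliberately not implemented; a pre-conformer callback slot is
where a pKa model would plug in. Duplicates are resolved first-seen-wins on
the canonical SMILES of the standardized largest fragment.

Conformers are embedded with ETKDGv3 (seeded; default seed 42, surfaced in
the CLI) from a pool of max(2n, 60) embeddings (RMS pruning 0.35 Å),
minimized and ranked by MMFF94 energy with a UFF fallback, then cut to the
n lowest-energy distinct geometries: 3 for the 3D circular fingerprint, up
to 20 for the 5D shape descriptor. The deep pool makes the selected
low-energy ensemble nearly independent of the embedding seed, which keeps
3D similarities reproducible across runs. Gasteiger partial
charges (e) and Wildman–Crippen atomic logP contributions (unitless) are
attached per atom — open, deterministic choices where the original
processing chain used commercial models.

## 2D fingerprints — pinned dialects

All hashed methods use one frozen 32-bit FNV-1a hash over little-endian
token streams (`simscreen.hashing`). Changing any tokenization detail
changes every stored fingerprint, so the dialects below are fixed.

**Path fingerprint (FP2-style), 2048 bits.** All simple linear paths of
1–7 atoms plus ring-closure fragments. Atom token = atomic number; bond
token = order with aromatic = 5; single-atom C/N/O fragments are excluded.
A linear fragment is read in its lexicographically smaller direction; a
ring fragment in its smallest rotation/reflection of the cyclic
(bond, atom) sequence. Each distinct fragment sets one bit. This follows
the classical path-fingerprint convention; the enumeration was checked to
reproduce the reference implementation's fragment sets on the worked
example below. Folding collisions mean folded Tanimoto values sit a few
hundredths above the unfolded fragment-set value; the worked-example
tolerance absorbs this.

**Extended-connectivity (ECFP4), 2048 bits.** Initial per-atom invariants:
atomic number, heavy-atom degree, total valence minus attached hydrogens,
hydrogen count, formal charge, ring membership — hashed to a 32-bit
identifier. diameter/2 update rounds hash (round, own id, sorted
(bond-token, neighbor-id) list). Each identifier covers a substructure,
tracked as its (atom set, bond set); duplicate substructures keep the
earlier-iteration, then smaller, identifier. Surviving identifiers fold
modulo the bit length; the unfolded identifier set is exposed for
fold-independent comparisons.

**MinHash (MHFP6), k = 2048.** Shingles are rooted SMILES of the circular
substructure of radius 1..3 (up to 6 bonds diameter) around each atom,
computed on a canonically renumbered copy of the molecule so the shingle
set is independent of input atom order. MinHash uses k universal-hash
permutations (a·x + b) mod (2³¹ − 1) with a fixed global seed (42) over
FNV-hashed shingles; similarity is the fraction of matching minima, the
unbiased Jaccard estimator (MAE < 0.02 at k = 2048 against exact Jaccard).

**2D pharmacophore, 2048 bits.** Feature typing by the SMARTS rules in
`data/pharmacophore_features.yaml` (donor, acceptor, cation, anion,
aromatic, hydrophobic; version 1, editable). A feature point is a merged
set of overlapping same-class matches; distances between points are the
minimum topological shortest path between their atom sets, binned at edges
(1, 2, 3, 4, 5, 6, 7, 8+) — the bin edges are a documented default, the
underlying method does not prescribe them. All 2-point pairs and 3-point
triangles are encoded as canonical tokens (sorted classes; for triangles
the lexicographically smallest labelled form over all six vertex
permutations) and hashed to bits. Pairs at distance 0 (overlapping points)
are skipped.

**Extended reduced graph (ErG).** Fused aromatic ring systems collapse to
centroid nodes; all other atoms are nodes; edges follow bonds between
nodes. Property points (the pharm2d features, with formal-charge-based
cation/anion typing and hydrophobic endcaps) attach to their node — a point
spanning several nodes attaches to its first non-ring node in canonical
order. For each property pair at reduced-graph distance d ≤ 15 the
(p_i, p_j, d) entry gains 1.0 and the d ± 1 entries gain the fuzz factor
(default 0.3, from the original method), clipped to [1, max_distance].
Scores use the algebraic Tanimoto a·b / (|a|² + |b|² − a·b).

## 3D descriptors

**5D shape descriptor (ES5D).** Atom i is embedded at (x, y, z, 25·qᵢ,
25·lᵢ): 25 Å per elementary charge as in the ElectroShape line of methods,
and the same scale for the lipophilicity axis (no published value exists;
one symmetric choice, configurable). Six reference points: the 5D
centroid; the atom farthest from it; the atom farthest from that; two
points displaced from the centroid along the normalized cross product of
the spatial parts of the two difference vectors by half the first vector's
length, with the charge coordinate at its maximum/minimum; and the
analogous point with the lipophilicity coordinate at its maximum. For each
reference the mean, population standard deviation, and signed cube root of
the third central moment of the atom distances give 18 components.
Rigid-motion invariant; mirror-sensitive only through the cross-product
references. Similarity is 1 / (1 + mean absolute component difference).
Degenerate cases: fewer than 2 atoms is a typed error; collinear geometries
have a vanishing cross product and the displaced references collapse onto
the centroid.

**3D circular fingerprint (E3FP-style), 1024 bits.** Hydrogens excluded.
Level-0 identifiers are the ECFP atom invariants. At level t, each atom's
shell covers atoms within t·1.718 Å; the shell hashes (level, own id,
sorted (member-id, bonded-flag, orientation-sign) tuples). The orientation
sign of a member is the sign of its projection onto the normal of the plane
spanned by the first two sorted members (tolerance 1e-4), which flips under
reflection, so enantiomers separate from level 2 while rotations and
translations leave the fingerprint unchanged. Shells covering an
already-covered atom set are dropped (earlier level, then smaller id,
wins). Defaults (level 5, multiplier 1.718, 1024 bits, 3 conformers)
follow the published optimized parameterization. Multi-conformer scoring
takes the maximum over all geometry pairs (best-match reading; mean
available). Note the documented caveat: independently generated conformer
ensembles of the same compound may score below 1.

## Screening

A query is fingerprinted once with the store's parameters and scored
against every entry; hits below the method threshold are dropped and the
rest ranked (descending score, ties by identifier, truncated at 400 by
default). The default thresholds {MHFP6 0.18, E3FP 0.2, ECFP4 0.25,
pharm2D 0.35, FP2 0.48, ErG 0.75, ES5D 0.83} are the published
probability-0.5 operating points for these methods. Scaffold searches
return only exact canonical-key matches (Murcko or generic Murcko) and emit
no score; the scaffold's ECFP4 fingerprint is a prefilter index only,
identity is never decided on a folded fingerprint. 3D and combined
screening refuse stores above 100k entries unless forced, reflecting their
cost. The combined method reports
logistic(β₀ + β_FP2·s_FP2 + β_ES5D·s_ES5D); the shipped coefficients
(−2.926, 5.297, 2.659) were fitted on this package's synthetic calibration
set and are *not* derived from published bioactivity data — supply your own
model for real collections.

## Threshold calibration

From a (compound, target) activity table the calibrator samples n_pos
distinct pairs sharing at least one target and n_rand uniform random pairs
(which may share a target by chance, uncorrected). Similarities are binned
(width 0.02 on [0, 1]); each occupied bin estimates
P = w·N_pos / (w·N_pos + N_rand) with w = (n_rand/n_pos)·prevalence_correction.
The default correction of 1 reweights the two samples to an effective 1:1
prior, making P = 0.5 a meaningful decision boundary regardless of the
sampling ratio; a real prior can be encoded through the correction factor.
An isotonic pass (count-weighted, on by default) enforces monotonicity.
The threshold is the lower edge of the first occupied bin whose smoothed
probability reaches the target level and stays there for all higher
occupied bins; a curve that never sustains the level is a typed error, not
a silent extrapolation. The combined logistic model is fitted by weighted
maximum likelihood (same reweighting); near-unregularized coefficients
beyond ~15 on these unit-range features are flagged as quasi-separation
and refitted with moderate L2. Standard errors come from the inverse
Fisher information at the fit.

## Synthetic data — what it emulates and what it does not

Real calibration corpora (tens of millions of annotated compound pairs)
cannot ship with a library, so `simscreen.synthetic` generates desk-scale
stand-ins. `generate_library` composes molecules from a weighted fragment
grammar with deterministic attachment, so a fragment sequence maps to one
molecule; in family mode it emulates congeneric series by varying two
designated positions of a fixed base sequence, giving the broad
within-series similarity spectrum of real R-group enumerations.
`plant_activities` controls the ground truth: in the default pair mode,
each positive draw creates a minimal two-compound activity group, so the
probability that two compounds share a target equals the planted link
evaluated at their mutual ECFP4 similarity exactly. The alternative anchor
mode (one target per anchor compound, membership by similarity to the
anchor) is more database-like but makes sharing transitive within
clusters: the induced pairwise curve then no longer equals the link, and a
class-balanced curve crosses 0.5 wherever a bin's share rate merely
exceeds the dataset average. Pair mode is therefore the right tool for
validating recovery of a planted threshold; anchor mode for qualitative,
database-like structure.

The packaged recovery experiment uses 2000 molecules in families of 25
(6–8 fragments), a step link at similarity 0.5, background noise rate 0.01
over 10 broad targets, and 10,000 positive / 100,000 random sampled pairs
(a 1:1000 scale-down of the corpus size the real calibration used) across
3 library seeds. Passing it shows the estimator and threshold extraction
are correct under the planted model; it does not show that any particular
published threshold is reproducible, since those derive from external
bioactivity data, nor that real similarity–activity relationships are
step-shaped.

## Worked example and tolerances

The reference pair losartan/olmesartan yields FP2 0.70, ECFP4 0.54, and
E3FP 0.27–0.29 (mean over 5 conformer seeds) under the pinned dialects,
against published values 0.72 / 0.55 / 0.30 computed with other toolchains'
hash dialects and fold lengths; the acceptance bands (±0.03 for 2D, ±0.05
for 3D) are the documented dialect allowance. Scores print rounded to 3
decimals; full precision is kept internally.

## Known limitations

- No protonation/tautomer state enumeration; fingerprints see the input
  state (after optional canonical-tautomer normalization).
- Bit-level compatibility with other packages' fingerprints is out of
  scope by design; only within-package comparisons are meaningful.
- The pharmacophore SMARTS rules are a curated minimal set (version 1),
  not a validated reproduction of any published feature definition file.
- MinHash signatures are large (k integers per molecule); the text store
  trades compactness for transparency.
- The quasi-separation heuristic (|β| > 15) is a pragmatic guard, not a
  formal test.
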