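# simscreen

Ligand-based virtual screening with calibrated similarity thresholds.

Given a query molecule and a compound library, `simscreen` finds library
members likely to share the query's bioactivity, following the similarity
principle: structurally similar molecules tend to act on similar targets.
It is aimed at drug-discovery scientists doing hit finding, scaffold
hopping, and early structure–activity exploration.

The package provides, as a library and a CLI:

- **Preparation** — SMILES/SDF parsing, salt stripping, element / size /
  weight filters (≥ 6 heavy atoms, MW ≤ 1500, organic element set),
  neutralization, de-duplication, seeded ETKDG conformer generation.
- **Seven fingerprint methods**, implemented from their algorithmic
  definitions: path-based FP2 (2048 bits), extended-connectivity ECFP4
  (2048 bits), MinHash MHFP6 (k = 2048), 2D pharmacophore triplets, the
  extended reduced graph (ErG) with fuzzy incrementation, the E3FP-style
  3D circular fingerprint (3 low-energy conformers), and the 18-component
  5D ElectroShape descriptor (up to 20 conformers, Gasteiger charges,
  Wildman–Crippen lipophilicity).
- **Similarity** — Tanimoto T(A,B) = |A∩B| / |A∪B| for bit sets, its
  algebraic form a·b/(|a|²+|b|²−a·b) for ErG vectors, the MinHash
  matching-minima estimator, and 1/(1 + mean|Δ|) for shape vectors;
  best-geometry aggregation across conformer ensembles.
- **Scaffold search** — exact Murcko and generic-Murcko (all atoms → C,
  all bonds → single) canonical-key matching.
- **Calibration** — probability-of-shared-target curves P(shared | s)
  estimated from positive and random compound pairs with class-balanced
  reweighting, isotonic smoothing, P ≈ 0.5 threshold extraction, and a
  combined 2D/3D logistic score
  P = σ(β₀ + β_FP2·s_FP2 + β_ES5D·s_ES5D).
- **Screening** with per-method calibrated thresholds
  (MHFP6 0.18, E3FP 0.20, ECFP4 0.25, pharm2D 0.35, FP2 0.48, ErG 0.75,
  ES5D 0.83) so hit lists from different methods are comparably enriched.
- **Synthetic fixtures** — seeded fragment-grammar libraries and planted
  compound–target activity tables with a known similarity→sharing link, so
  the whole stack is testable without downloading any database.

See `docs/methods.md` for the models, pinned hash dialects, and numerical
choices.

## Worked example

Losartan and olmesartan, two angiotensin-II receptor blockers, scored with
three methods:

```python
import simscreen as ss

kept, _ = ss.prepare_library([
    ("losartan",   "CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1"),
    ("olmesartan", "CCCc1nc(C(C)(C)O)c(C(=O)O)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1"),
])
a, b = kept
print("FP2  ", round(ss.tanimoto(ss.fp2_fingerprint(a),  ss.fp2_fingerprint(b)),  2))
print("ECFP4", round(ss.tanimoto(ss.ecfp_fingerprint(a), ss.ecfp_fingerprint(b)), 2))

ca = ss.generate_conformers(a, 3, seed=1)
cb = ss.generate_conformers(b, 3, seed=1)
print("E3FP ", round(ss.multi_conformer_similarity(
    ss.e3fp_fingerprints(ca), ss.e3fp_fingerprints(cb), ss.tanimoto), 2))
```

prints

```
FP2   0.7
ECFP4 0.54
E3FP  0.27
```

The same pair scores differently under different encodings — path
fingerprints see the shared biphenyl-tetrazole backbone, circular
fingerprints penalize the differing imidazole substituents, and the 3D
method is stricter still. That is why each method carries its own
calibrated threshold: 0.70 is a confident FP2 hit (threshold 0.48), and
0.54 a confident ECFP4 hit (threshold 0.25), while the same numeric value
would mean little for ES5D (threshold 0.83).

From the shell:

```sh
simscreen synth --n 1000 --seed 1 -o lib.smi
simscreen prep lib.smi -o prepped.smi
simscreen fp prepped.smi --method ecfp4 -o lib.fps
simscreen screen --query "CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1" \
    --store lib.fps -o hits.csv
```

`hits.csv` lists hits as `id,score,rank,method` with scores at or above
the method threshold, ranked by descending similarity.

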