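# toplap

Persistent-Laplacian featurization and accuracy evaluation of predicted
protein–protein complexes, with a cross-validated regression stage for
mutation-induced binding free energy changes (ΔΔG).

## The problem

Structure predictors now emit whole protein–protein complexes together with
confidence scores (ipTM for the interface, pTM for the global fold). Before
such models are used for downstream tasks — above all predicting how a point
mutation shifts a complex's binding free energy — three questions need
quantitative answers:

1. **How close is the predicted complex to the experimental one?**
   Superposition RMSD, per-residue backbone RMSD, and whether the local error
   tracks crystallographic flexibility (B-factors).
2. **Do the predictor's own confidence scores flag the bad cases?**
   ipTM > 0.8 marks a high-confidence interface, ipTM < 0.6 a likely-incorrect
   one, with an ambiguous band in between; pTM ≥ 0.5 an acceptable global fold.
3. **Are the structures good enough to featurize?** Element/site-specific
   persistent-spectral descriptors feed a gradient-boosted regressor whose
   10-fold cross-validated Pearson correlation (R_p) and RMSE (kcal/mol) are
   the standard ΔΔG benchmarks.

This package implements that full evaluation pipeline at desk scale. A
synthetic-data module generates two-chain complexes with controlled
flexibility, perturbed "predicted" copies, point clouds of known topology and
ΔΔG tables with planted signal, so every stage is testable without any
external downloads. The same code paths accept real PDB/mmCIF structures,
prediction-server confidence JSON, and SKEMPI-style mutation tables.

## The mathematics at the core

Atoms around a mutation site are grouped into four subsets (the site, its
r-neighborhood, and each partner's binding-site atoms) intersected with
element groups such as {C}, {N}, {O}. Cross-subset contacts are encoded by a
modified distance D_mod that *excludes* same-subset pairs (they are pushed
beyond every filtration scale), so only interactions between the two sets
form simplices.

From each point cloud a filtration — Vietoris–Rips for dimension 0, Alpha
(Delaunay-restricted) for dimensions 1–2 — produces a nested family of
simplicial complexes K_t. On each snapshot the k-combinatorial Laplacian

    L_k = B_{k+1} B_{k+1}ᵀ + B_kᵀ B_k,   L_0 = B_1 B_1ᵀ,

is assembled from signed boundary matrices B_k over the reals. By the
combinatorial Hodge theorem the multiplicity of its zero eigenvalue equals
the Betti number β_k (components, loops, cavities); the nonzero part of the
spectrum — the nonharmonic spectrum — adds geometric shape information that
homology alone misses. Tracking β_k and nonharmonic summary statistics
(min, max, mean, sd, sum, count) along the filtration grid yields the
feature vector for the ΔΔG regressor.

The structure-evaluation side uses Kabsch superposition on mapped backbone
atoms, per-residue RMSD under the single global transform, Shrake–Rupley
relative accessible surface area (rASA), and the five-way residue
classification at the 25% rASA cutoff: non-interface residues are *interior*
(buried) or *surface* (exposed); interface residues (any measurable burial
upon complexation) are *support* (buried already as a monomer), *core*
(exposed as monomer, buried in the complex) or *rim* (still exposed).

## Worked example

```python
import numpy as np
from toplap import (
    SynthConfig, make_toy_complex, perturb_structure, per_residue_rmsd,
    make_ddg_table, DdgBoostModel,
)

# A 100-residue two-chain complex with a flexible segment, and a
# "predicted" copy whose displacement scales with B-factor.
ref = make_toy_complex(SynthConfig(n_residues=50, flex_span=(20, 33), seed=3))
pred = perturb_structure(ref, "flexible", amplitude=1.0, seed=11)
report = per_residue_rmsd(ref, pred)
print(f"global backbone RMSD: {report.global_rmsd:.3f} Å")

from scipy.stats import spearmanr
rho = spearmanr(report.per_residue["bfactor"], report.per_residue["rmsd"]).statistic
print(f"Spearman(B-factor, per-residue RMSD) = {rho:.3f}")

# ΔΔG cross-validation on a table with planted spectral signal.
ds = make_ddg_table(n_complexes=10, mutations_per_complex=15,
                    r2_target=0.99, seed=5)
y = np.array([r.ddg for r in ds.records])
model = DdgBoostModel(ds.features, y,
                      params={"n_estimators": 600, "learning_rate": 0.05})
print(model.crossvalidate(folds=10, seed=1).summary())
```

Output:

```
global backbone RMSD: 2.182 Å
Spearman(B-factor, per-residue RMSD) = 0.754
10-fold cross-validation — ΔΔG prediction
====================================================
records                                        150
fold grouping                        mutation_pair
seed                                             1
pooled R_p                                   0.991
pooled RMSE (kcal/mol)                       0.098
per-fold R_p                          0.990 ± 0.006
per-fold RMSE                         0.097 ± 0.016
...
```

The RMSD of ~2 Å is dominated by the flexible segment (the rigid part of
the perturbation is removed exactly by the superposition); the strong
Spearman correlation recovers the injected B-factor–displacement link; and
the pooled R_p near the planted signal ceiling shows the spectral features
carrying the ΔΔG signal through the cross-validation protocol.

A thin CLI mirrors the library:

```bash
toplap-eval simulate --preset ddg-table --seed 7 -o fixtures/
toplap-eval features --mutations fixtures/mutations.csv --structures fixtures/ \
    --small-config -o features.csv
toplap-eval cv --features features.csv --folds 10 --seed 42
toplap-eval evaluate --ref ref.pdb --pred pred.cif --confidence pred.json -o report/
```

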