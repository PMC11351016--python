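# Methods

This note documents the models, conventions and numerical choices behind
`toplap`, and what the synthetic-data experiments do and do not establish.

## Atom subsets and the modified distance

For a mutation at a resolved residue, four atom subsets are built on the
wild-type geometry: the **site** (all atoms of the mutated residue), the
**neighborhood** (atoms of other residues within `r` of any site atom), and
the **P1/P2 binding sites** (each partner's atoms within `r` of the other
partner). The selection radius defaults to `r = 10 Å` and is a configuration
key, not a constant: it brackets the non-bonded interaction distances that
dominate interface energetics, and the nesting property (larger `r` gives a
superset) is tested. Subsets are intersected with element groups; the
default cross-set menu pairs {C}–{C}, {C}–{N}, {C}–{O}, {N}–{N}, {N}–{O},
{O}–{O}, covering the hydrophobic C–C and hydrophilic N/O contact types.
Hydrogens are kept in the data model but never selected by these groups.

The modified distance over a pair of subsets keeps the Euclidean distance
between atoms of *different* subsets and **excludes** same-subset pairs.
Exclusion is represented as a boolean mask; when a dense matrix is needed,
excluded entries take a sentinel strictly greater than the maximum
filtration scale, so they can never form a simplex and no infinities enter
numeric kernels. Because this construction is not an embedding, modified-
distance features are dimension-0 only (Vietoris–Rips); dimensions 1–2 use
Alpha complexes on raw coordinates.

## Filtrations

**Vietoris–Rips** (dimension 0): vertices at scale 0, an edge at its
distance, higher simplices at the maximum of their edge values (diameter
convention). The VR scale is therefore an *edge length* in Å.

**Alpha** (dimensions 1–2): simplices of the 3-D Delaunay triangulation
(scipy Qhull). Each simplex's value is its squared circumradius if its
circumsphere is empty of other points (Gabriel), otherwise the minimum of
its cofaces' values, propagated downward dimension by dimension — the
standard alpha algorithm. Values are reported as radii (square roots) so VR
and Alpha grids share Å units; note the factor-of-two relation between the
two conventions (an isolated pair connects at `d` in VR, at `d/2` in
Alpha). Degenerate inputs (collinear/coplanar clouds, which synthetic
lattices produce readily) get a deterministic Gaussian jitter of 1e-6 Å
from a fixed-seed generator before triangulation. Alpha values are verified
in tests against a definitional oracle: the value of a Delaunay simplex is
recomputed as a convex QP (minimum distance from the simplex's Voronoi
face to its vertices), agreeing to 1e-6.

Default filtration grids: 0–12 Å in 0.25 Å steps for VR, 0–10 Å in 0.25 Å
steps for Alpha. The compact cohort configuration (`FeatureConfig.small()`)
uses dimension-0 blocks only on a 1.5 Å grid with the two extreme element
pairings; it exists because the full configuration costs ~10 s per mutation
while cohort experiments need hundreds of rows.

## Spectra

Chains carry real coefficients; boundary matrices use the sorted-vertex
orientation with the standard sign rule ((−1)^i on the face omitting the
i-th vertex). `L_k = B_{k+1}B_{k+1}ᵀ + B_kᵀB_k`, `L_0 = B_1B_1ᵀ`.
Eigenvalues below `1e-8 · max(1, λ_max)` count as harmonic — a scale-aware
cutoff that survives unit changes; their count is β_k (combinatorial Hodge
theorem, property-tested against rank–nullity and against an independent
GF(2) persistence reduction). Nonharmonic statistics are min, max, mean,
sd, sum and count; an empty spectrum contributes zeros with count 0, and
empty atom subsets produce zero blocks flagged in the layout descriptor.
Dense eigensolvers are used up to order 2000; above that only the extremal
ends of the spectrum are computed and the result is flagged truncated.
The p-persistent Laplacian (operators across a pair of scales) is *not*
implemented; only snapshot operators L_k(K_t) feed the features.

## Structure evaluation

Chain correspondence is established by global sequence alignment of every
reference–prediction chain pair (Needleman–Wunsch scoring via Biopython)
with greedy assignment maximizing identity, robust to renamed or reordered
chains; a best pairing under 30% identity is rejected as a likely file
mismatch. Superposition uses one Kabsch fit on the backbone atoms
(N, CA, C, O present on both sides) of all mapped residues; the global RMSD
and every per-residue RMSD are measured under that single transform — no
per-residue refitting — so local deviations are read against the rigid
global frame. Missing residues are excluded and counted, never imputed.
Collinear point sets are rejected (rotation underdetermined).

Shrake–Rupley accessible surface area uses 960 golden-spiral sphere points,
a 1.4 Å probe, and standard van der Waals radii (C 1.70, N 1.55, O 1.52,
S 1.80 Å; unknown elements fall back to 1.70 with a warning). Per-residue
ASA is normalized by the Tien-2013 theoretical maximum to give rASA. Since
those maxima are defined in tripeptide context, fully solvent-exposed
isolated or terminal residues can exceed rASA = 1; the classification rules
only compare against the 25% cutoff, so this is harmless.

Region classes: a residue is *interface* when its monomer-vs-complex rASA
difference is at least 0.001 — any measurable burial counts, with the small
epsilon guarding numeric noise from the sphere-point quadrature. Interface
residues split into support (monomer rASA < 25%), core (monomer ≥ 25%,
complex < 25%) and rim (complex ≥ 25%); non-interface residues into
interior (< 25%) and surface. Confidence thresholds are ipTM 0.8 (high)
and 0.6 (likely incorrect), pTM 0.5.

## ΔΔG regression

The design matrix concatenates spectral blocks (wild-type geometry only; no
mutant side-chain rebuilding), one-hot wild-type and mutant residues, the
mutated residue's one-hot region class, and an optional externally supplied
embedding block joined on the record id. Direct/reverse augmentation
(reverse = swapped amino acids, negated ΔΔG) defaults on; a mutation and
its reverse always share a cross-validation fold. Records whose structure
or residue cannot be resolved go to an exclusion report rather than being
silently dropped.

The learner is gradient-boosted trees (xgboost): depth 7, learning rate
0.01, a 10,000-round ceiling cut short by early stopping (50 rounds) on a
5% validation slice, single-threaded for determinism. Folds are assigned
per mutation pair by default — the common record-level protocol — with a
`group_by_complex` switch whose anti-leakage effect is regression-tested
(a pure per-complex offset is learnable only with record-level folds).
Cohort-scale tests override the ensemble to 600 rounds at rate 0.05; at a
few hundred rows this reaches the same recovery at a fraction of the cost.

## Synthetic data: what it emulates, what it does not

`make_toy_complex` builds two poly-alanine chains (N, CA, C, O, CB with
correct elements) on an idealized α-helical backbone (2.3 Å helix radius,
1.5 Å rise, 100° turn ≈ 3.8 Å Cα spacing), mirrored and translated so the
closest inter-chain approach equals the configured gap (default 4.5 Å, a
typical interface contact distance). B-factors are flat at the baseline
(20 Å²) except over a flexible segment (default a quarter of each chain)
multiplied by 5. A segment covering ~25% of residues makes the rank
correlation between the two-level B-factor and the continuous per-residue
RMSD informative; much smaller segments cap the attainable Spearman near
0.5 for purely combinatorial reasons.

`perturb_structure` emulates a predicted copy: a random rigid motion
(recovered exactly by superposition) plus, in flexible mode, per-residue
isotropic Gaussian displacement with sd proportional to B-factor
(sd_i = amplitude · B_i / mean B) — the simplest mechanism producing the
monotone flexibility-vs-error trend. `make_ddg_table` computes real
spectral features for every synthetic mutation and plants a sparse linear
signal (3 standardized feature columns, Gaussian coefficients) with noise
scaled to a target R²; the generator returns ground truth for recovery
assertions, and its empirical R² is simulation-checked against the target.

Passing these tests shows the pipeline's mechanics are correct — subsets,
spectra, superposition, classification, cross-validation — under controlled
conditions. It does not certify performance on real complexes: the
synthetic geometry has no side-chain diversity, no sequence realism, no
rotamers or energy minimization, its ΔΔG is linear in features by
construction, and real mutation effects involve physics (packing,
electrostatics, entropy) that no geometric feature set fully captures.
Reproducing literature-scale benchmark numbers additionally requires the
external mutation database, deposited predicted structures and their PDB
references, which the pipeline accepts through the same interfaces.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`, chosen as the
smallest sizes at which each property is stable: 100 random complexes
(6–12 vertices) for the Hodge checks; 3-D clouds of 20–50 points for the
persistence-oracle comparison; 100-residue complexes and 5 seeds for the
flexibility recovery; 100–500-record tables, 10 complexes or more, for the
cross-validation recovery (planted R² = 0.99 and 0.8, and the pure-noise
null averaged over 3 seeds).

## Known limitations

* Alpha complexes assume points in general position after jitter; exactly
  duplicated atoms must be deduplicated upstream (merged subset clouds are).
* The truncated eigensolver branch (order > 2000) reports extremal
  eigenvalue statistics only; Betti counts there refer to the computed end
  of the spectrum.
* Sequence-identity chain mapping assumes protein chains; nucleic acids are
  out of scope, as are ligands and covalent modifications.
* The regression stage models single mutations; multiple simultaneous
  mutations and backbone-rebuilt mutant structures are out of scope.
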