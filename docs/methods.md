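# Methods

## Scope and model

`spirospace` treats bioisostere identification as unsupervised structure
discovery in descriptor space. The underlying assumptions are:

1. A scaffold's replaceability is captured by a moderate number of global
   physicochemical descriptors (size, lipophilicity, polarity, shape,
   electrostatics, strain) rather than by substructure matching.
2. Euclidean distance in a standardized, decorrelated, PCA-projected
   descriptor space is a meaningful (dis)similarity: rings that cluster
   together, or that sit closer to a reference than that reference's own
   cluster neighbors, are candidate bioisosteres.
3. One low-energy conformer per scaffold is representative. Small rigid
   rings (≤ ~10 heavy atoms) have few conformers, so the best-of-n embedding
   is adequate; the single-conformer assumption is flagged in provenance and
   would need revisiting for flexible scaffolds.

## Geometry

Conformers come from ETKDG distance-geometry embedding followed by MMFF94
minimization (UFF for species MMFF cannot parametrize), best of `n_starts`
independent starts. Defaults `n_starts = 10`, `seed = 2025`: enough starts
that the best minimized energy is stable for rings of this size, and fixed
seeding makes every coordinate bit-reproducible. Start *i* uses seed
`seed + i`, so the best-of-n energy is non-increasing in `n_starts` by
construction. Partial charges are Gasteiger (iterative
electronegativity-equalization); they are what the dipole uses, so dipoles
are empirical-charge dipoles, not QM dipoles.

Externally optimized geometries (e.g. DFT) can be imported from XYZ with
optional electronic/Gibbs energies in hartree; imported coordinates are never
re-minimized and energies are stored untouched with a unit tag. Imported
charges may accompany the geometry; otherwise charges default to zero and
charge-derived descriptors from imported geometries should be interpreted
accordingly.

## Descriptors

The registry is fixed and versioned (its hash is recorded in every run
manifest): 3 one-dimensional, 8 two-dimensional and 5 three-dimensional
descriptors. 1D/2D values come from RDKit (molecular weight, heteroatom and
heavy-atom counts, Crippen logP, TPSA, H-bond donors/acceptors, rotatable
bonds, fraction Csp³, ring count, QED). QED is the documented
desirability-style drug-likeness score; its weight table is RDKit's published
default. The 3D descriptors are implemented here because their exact
conventions drive the downstream distances:

- **Plane of best fit**: heavy atoms only (the published convention for this
  descriptor); least-squares plane through the centroid, normal along the
  smallest-eigenvalue eigenvector of the coordinate covariance; value is the
  mean absolute point-plane distance; any ≤ 3-point set is exactly planar,
  so the value is 0 by definition.
- **Asphericity**: gyration tensor of unweighted coordinates (all atoms);
  A = [(λ₁−λ₂)² + (λ₁−λ₃)² + (λ₂−λ₃)²]/[2(λ₁+λ₂+λ₃)²]. Mass weighting is
  available but off by default so the descriptor reflects shape, not isotope
  bookkeeping.
- **Dipole**: |Σ qᵢrᵢ| × 4.80320 D/(e·Å). For net-charged species the value
  is origin-dependent and a warning is attached.
- **Volume**: union of Bondi vdW spheres counted on a cubic grid
  (default spacing 0.2 Å; the box is padded by max radius + 2 spacings).
  The grid is laid in the canonical principal-axes frame (axis signs fixed
  by the largest-magnitude projection), which makes the value independent of
  the conformer's input orientation — a grid over raw coordinates would not
  be. At 0.2 Å the discretization error on these rings is well under 2%.
- **Strain energy**: two modes. `external_qc` converts a supplied
  (E_cyclic − E_reference) hartree difference (× 627.5095 kcal/mol per
  hartree) and is the route for replicating QC-level strain schemes.
  `ff_proxy` (default, loudly flagged "proxy" in reports) cleaves one bond
  per ring — preferring single bonds, then C–C bonds, then lowest atom
  indices, kekulizing before each cleavage — caps the valences with
  hydrogens, and reports the force-field energy difference between the
  minimized ring and the minimized open-chain analogue. The proxy changes
  stoichiometry by 2 H per cleaved bond, so it is *not* a thermochemical
  strain energy; it is a deterministic, self-contained quantity that
  preserves strain ordering (three-membered ≫ six-membered rings), which is
  what the Δ-comparison needs.

## Feature preparation

Constant columns are dropped (with a log), then columns are z-scored with
the sample (n−1) standard deviation. VIF pruning removes the worst offender
while any log₁₀ VIF ≥ 5 (i.e. R² ≥ 1 − 10⁻⁵ of that descriptor regressed,
with intercept, on the others), recomputing VIFs after each removal.
Iterative worst-first removal, rather than one-shot simultaneous removal,
avoids over-pruning when several descriptors share one collinear relation;
ties break toward the larger VIF and then the alphabetically first name so
the removal sequence is unique. Perfect collinearity is reported as
VIF = ∞ (the least-squares fit uses the pseudoinverse, so rank-deficient
designs do not crash). A lone surviving column has VIF 1 by definition; if
even that breaches the threshold (threshold ≤ 0) the pruner raises rather
than silently emptying the matrix.

## Chemical-space mapping and clustering

PCA is an eigendecomposition of the sample covariance of the standardized
matrix. Eigenvector signs are pinned (largest-magnitude loading positive) so
scores are reproducible. Distances and reports use the first 3 components;
cluster fitting uses the components covering ≥ 90% of variance (at least 3),
both recorded in the manifest. The 3-component choice for distances keeps
reported scaffold–scaffold distances interpretable in the visualizable
space; the fit dimensionality is configurable.

k-medoids is classic PAM: BUILD picks the point minimizing total distance,
then greedily adds the medoid with the largest cost decrease; SWAP applies
the single best improving (medoid, non-medoid) exchange until none improves.
All ties break to the lowest index, making the algorithm deterministic with
no random restarts. PAM is a *local* search: its swap optimum can differ
from the exhaustive-enumeration optimum even on small instances (observed on
~7% of iid-Gaussian instances with n ≤ 10, k = 3 — the same rate as the
reference R implementation of PAM). On clusterable data the gap essentially
vanishes; the test suite pins exact-optimality on structured instances and
cost-descent monotonicity everywhere.

Silhouette uses the standard conventions: a(i) is the mean distance to own
cluster's other members, b(i) the smallest mean distance to another cluster,
s(i) = (b−a)/max(a,b); members of singleton clusters score 0; the selection
criterion is the unweighted mean, and ties in the k scan resolve to the
smaller k.

## Bioisostere report

Per-scaffold intra-cluster statistics are the mean and sample sd of
distances to the scaffold's cluster mates (singletons flagged, two-point
clusters have a mean but no sd). Candidates are ranked by distance to the
reference; Δ Value % = 100 × (candidate − reference)/|reference| so that the
sign always means direction of change even for negative-valued descriptors;
a zero reference leaves the cell undefined (NaN) rather than ±∞.

## Thermochemistry

`reaction_free_energy` is pure bookkeeping over externally computed Gibbs
energies: ΔG = (Σ products − Σ reactants) × 627.5095 kcal/mol, positive =
endergonic. Species carry method/basis/solvent provenance and the module
enforces it, because a ΔG without its level of theory is not auditable.
No thermal corrections or conformer searches are done in-process.

## Synthetic data

The generator draws cluster c's rows from an isotropic Gaussian
N(μ_c, σ² I_p) and appends near-collinear columns as weighted sums of latent
columns plus Gaussian noise (noise sd 10⁻³ by default, which places their
VIF far above the pruning threshold). Centers sit on a randomly rotated
regular simplex so that *every* pairwise center distance equals the stated
separation — with irregular center layouts "the separation" is not a single
number, and cluster-number selection is then confounded by the layout's
shape rather than its scale. The default specification mirrors the real
screen's scale: 5 clusters over 88 scaffolds, 13 latent + 3 collinear
descriptors, unit within-cluster sd. The recovery experiment re-derives each
replicate's seed from an independent child of the experiment seed, so any
replicate can be reproduced alone. Label agreement uses the adjusted Rand
index (chance-corrected pair counting), implemented in-package and
cross-checked against scikit-learn in the tests.

What the generator does *not* emulate: real descriptor marginals are skewed
and bounded (counts, fractions), clusters in real chemical space are
anisotropic and unbalanced, and descriptor noise is structural rather than
additive. Passing recovery tests therefore demonstrates the correctness of
the statistical machinery, not that real scaffold families are this
separable. At pairwise separation 10× the within-cluster sd the pipeline
recovers the planted k in ≈100% of replicates; near 5× the mean-silhouette
criterion becomes genuinely noisy (~89% recovery under the same
configuration), which is a property of silhouette-based model selection, not
of the implementation.

## Problem sizes and determinism

Default end-to-end runs use the 94-record builtin library, 10 embedding
starts, 0.2 Å volume grids, k scanned over 2..10 — about 15 s on one CPU —
and write a manifest with config hash, registry hash and SHA-256 checksums
of every output; re-running a manifest reproduces every file bit-for-bit on
the same platform. Recovery experiments default to 3 × 20 points, 6 + 2
descriptors, 100 replicates (a few seconds). The PAM-vs-enumeration
comparison uses 200 instances with n ≤ 10, k ≤ 3, where exhaustive
enumeration is exact and cheap.

## Known limitations

- Force-field geometries, Gasteiger charges and the strain proxy are
  self-contained stand-ins for QC-level inputs; absolute 3D descriptor
  values shift at other levels of theory (the import path exists precisely
  for that), though rankings of close analogues are more stable.
- The builtin reference panel is a curated default, not a canonical
  database; swap in your own SMILES/SDF file for exact replication of an
  external screen.
- Silhouette-selected k on real, weakly separated chemical families is
  noisy; inspect the full silhouette curve (always persisted) rather than
  trusting the argmax blindly.
- PAM guarantees a swap-local optimum, not the global one.
- Δ Value % is undefined for zero-valued reference descriptors and
  unstable for near-zero ones (e.g. dipoles of nearly apolar references).
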