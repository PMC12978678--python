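# Methods

`strokemap` implements multivariate lesion-symptom mapping (LSM) for
stroke cohorts at two spatial levels: voxels of a common-space lesion mask
(SVR-VLSM) and edges of a structural connectome (SVR-CLSM). This note
describes the statistical model, the conventions and numerical choices the
implementation commits to, what the synthetic-cohort generator does and
does not emulate, and known limitations.

## The analysis model

For one behavioral contrast, the data are a patients × features binary
matrix `X` (1 = voxel lesioned, or edge disconnected), a behavioral target
`y` (pooled accuracy on the target stimulus classes), and a covariate
block `C` containing the fixed nuisance covariates — lesion volume (cm³),
age (years), education (years) — plus the contrast's behavioral control
accuracies (e.g., real-word accuracy when the target is pseudoword
accuracy). Behavioral and nuisance covariates are handled by one
mechanism: both sides are residualized,

    X* = X − [1, C] B_X,    y* = y − [1, C] b_y,

with ordinary least squares, before any model fitting. Residual columns
are orthogonal to the intercept and every covariate column (enforced to
1e-8 in tests); residualization is idempotent.

An epsilon-insensitive support vector regression of `y*` on `X*` (linear
kernel, C = 1.0, epsilon = 0.1 by default) yields a feature-space beta map
by back-projection through the dual coefficients:

    beta_j = Σ_i alpha_i X*_ij   (support vectors only),

which for the linear kernel equals the primal weight vector exactly; for
the optional rbf kernel the same formula is used as a sensitivity-style
approximation. Damage is coded 1 and larger `y` is better performance, so
deficit-related features carry **negative** betas; all inference is
one-tailed negative.

Feature-wise significance uses a permutation null: permutation *b*
shuffles the residualized target with the seeded generator
`default_rng(seed + b)` and refits; the add-one rank formula

    p_j = (1 + #{b : beta_j^(b) ≤ beta_j^obs}) / (n_perm + 1)

guarantees p > 0 with floor 1/(n_perm+1). Covariates have already been
removed from both sides, so the rows of `(X*, y*)` are exchangeable under
the null and label shuffling is a valid permutation scheme. Shuffling the
*residualized* target (rather than re-residualizing each permuted raw
target) is a deliberate simplification in the Freedman–Lane spirit.

### Voxel level: clusterwise familywise-error correction

Voxels lesioned in at least 10% of patients (≥, equality included) enter
the design. Suprathreshold voxels are those with permutation p below the
cluster-forming threshold (default 0.005); connected components under the
configured adjacency (6/18/26, default 26) form clusters. The null
distribution of the maximum cluster size is built by thresholding *each
permutation's own p-map* — permutation *b*'s p at feature *j* counts
permutations (itself included, playing the add-one role) with beta ≤ its
own: p_j^(b) = rank / (n_perm + 1), the Westfall–Young convention — and
recording the largest component. A cluster is significant when

    p_cluster = (1 + #{b : max-size^(b) ≥ observed size}) / (n_perm + 1) < alpha.

The cluster-forming statistic is the permutation p (not raw beta), and the
cluster mass statistic is voxel count. Reporting follows field
conventions: size in cm³ to 3 decimals, unweighted center of mass of the
voxel centers in mm to 1 decimal, rows sorted by p then size.

### Edge level: disconnectomes and single-step maxT

A patient's binary disconnectome marks an edge as lesioned exactly when
the connection is **absent in the patient** (weight 0, tolerance 1e-12 for
float inputs) **and present in 100% of controls**; edges absent in any
control are excluded from analysis entirely, since their absence cannot be
attributed to the stroke. Only upper-triangle edges disconnected in
*strictly more than* 10% of patients are analyzed — note the deliberate
asymmetry with the voxel filter (≥ for voxels, > for edges), mirroring the
different inclusion rules the two analyses use.

Edge-level correction is single-step maxT (for a negative tail, min-beta):
the null statistic per permutation is the minimum beta over edges, and

    p_fwer,j = (1 + #{b : min_k beta_k^(b) ≤ beta_j^obs}) / (n_perm + 1).

Connectome space has no spatial contiguity to exploit, so cluster-based
correction would be arbitrary there.

### Parcel level

Parcel-level evaluation aggregates each parcel's retained incident edges
with the statistic Σ max(−beta, 0) (sum of negative parts), against a
max-statistic null over parcels computed on the *same* permutation stream
as the edge analysis. This aggregation is a package decision — the
parcel-level statistic is genuinely open in this family of methods — and
`parcel_statistic` is the single function to swap for alternatives (min
incident p, count of suprathreshold edges). Parcels with no retained
incident edge are reported as not analyzable rather than p = 1.

## Synthetic cohorts

The generator produces complete cohorts — lesions, connectomes, behavior,
with exported ground truth — whose statistical structure matches what the
analysis assumes, at a desk scale where hundreds of full pipeline runs
finish in minutes.

* **Grid and atlas.** 20 × 24 × 20 voxels at 2 mm isotropic: large enough
  for clusters to form, small enough that a 500-permutation run takes
  about a second. K = 4 seeded-Voronoi parcels per hemisphere (8 total),
  with voxelized straight-line "tract trajectories" between all left
  parcel pairs and homotopic left–right pairs (10 edges).
* **Lesions.** Single 26-connected left-hemisphere components grown by
  stochastic accretion from a seed voxel, biased (probability 0.7) toward
  a designated perisylvian territory. Target voxel counts are lognormal
  with (μ, σ) = (5.5, 0.75) in voxel units: mean ≈ 320 voxels ≈ 2.6 cm³,
  coefficient of variation ≈ 0.87 — the lesion-volume CV of a real
  64-patient left-hemisphere stroke cohort (mean 90.2, SD 78.2 cm³),
  scaled to the toy grid.
* **Connectomes.** Control edge weights are base 10.0 with ±10%
  multiplicative noise; 10% of edges are "unreliably present" (zeroed in
  30% of controls) to exercise the present-in-all-controls filter. A
  patient edge is zeroed exactly when the lesion intersects its
  trajectory, so every disconnection is causally logged.
* **Behavior.** Per class (200 real words; 20 each of 0M/1M/MM
  pseudowords), n_correct ~ Binomial(n, p) with
  logit(p) = baseline + β_age·age_z + β_edu·edu_z − w·damage.
  Baselines are the control-group mean accuracies of the emulated study
  (real 94.3%, 0M 89.7%, 1M 94.3%, MM 93.2%); covariate coefficients are
  −0.2 (age) and +0.2 (education) per SD on the logit scale, modest
  values of the order behavioral models report. `damage` is the damaged
  *fraction* of the critical region (graded — gives the voxelwise
  analysis a recoverable gradient) or the 0/1 disconnection of a critical
  edge (binary — matches the edge design matrix). Ages are N(61.6, 11.5²)
  truncated to [31, 92]; education N(16.5, 2.8²) truncated to [9, 21].
  With all effect weights 0, behavior is independent of the lesions — the
  null configuration used for familywise-error measurement. Per-item
  durations are lognormal, capped at the 10 s trial timeout, and used
  only by behavior-level analyses (durations are a control-group measure
  in the emulated design, not an LSM dependent variable).

What the generator does **not** emulate: vascular anatomy (lesions are
isotropic blobs, not territory-shaped infarcts), spatial covariance of
real lesion masks beyond contiguity, item-level psycholinguistics
(frequency/regularity/imageability), graded tract damage (edges are cut
or intact), and any spatial autocorrelation in behavior beyond what the
damage model induces. Passing tests therefore certify the *statistical
machinery* — error control, filters, determinism, recovery under the
stated generative model — not performance on real imaging data.

## Numerical and design choices

* **Dependent variable scale.** Raw accuracy proportions, not logits (an
  optional empirical-logit transform is available via
  `logit_transform`). The emulated analyses do not state a transform;
  proportions keep the variable in [0, 1] and the residualization linear.
* **Design normalization.** `SvrConfig.normalize_design` (default on)
  rescales the whole feature matrix by one global constant so the mean
  squared row norm is 1. Relative column scales — lesion-frequency
  information — are untouched, C keeps one meaning across designs of
  different width, and the SMO solver is well conditioned (raw binary
  designs with ~1000 columns produce Gram entries in the hundreds and
  pathological iteration counts). Applied identically to observed and
  permuted fits, so permutation validity is unaffected.
* **Target standardization.** `y*` is scaled to unit variance after
  residualization (`standardize_y`, default on), fixing the meaning of
  epsilon across contrasts. Permutation preserves the multiset of values,
  so standardizing before permuting is equivalent to after.
* **Ties and determinism.** Permutation p-values use sorted-search
  counting, exact under ties (betas can tie at 0 when a permuted target
  sits entirely inside the epsilon tube). Every random element — lesion
  growth, connectome noise, behavior draws, permutation shuffles — derives
  from named seeded generators; regenerating a cohort or rerunning an
  analysis with the same seed is bitwise identical, including written
  files.
* **Voxel volume.** Computed as the scalar triple product of the affine's
  3 × 3 block, exact (no LU round-off) for axis-aligned template affines;
  volumes report in cm³ to 3 decimals.
* **p-map sentinel.** Voxels outside the analyzed set carry 0.0 in
  written p-maps; a permutation p is never 0, so the sentinel is
  unambiguous.
* **Degenerate inputs.** Empty designs (no covered voxel, no retained
  edge) raise a dedicated error; a contrast retaining fewer than 10
  subjects refuses to run; an all-suprathreshold-free map returns an
  empty cluster list (not an error).

## Known limitations

* **Per-voxel sensitivity and localization sharpness.** At the default
  desk scale, lesions (~320 voxels) are three times larger than a
  100-voxel critical region, and lesion volume — which carries much of
  the damage signal — is residualized out by design. The resulting
  per-voxel signal is diffuse: seeded-region recovery experiments
  (`strokemap.experiments.vlsm_recovery`) localize the region's
  *neighborhood* (significant clusters with centroids 1–3 voxels from the
  truth centroid) but Dice overlap with the exact 100-voxel truth set
  stays low (~0.05 for the SVR map; even a univariate permutation
  statistic, strictly more sensitive per voxel in this regime, reaches
  only ~0.15–0.35). This is the well-known spatial blur of
  lesion-symptom mapping, not a property of the implementation; the
  edge-level analogue (one critical edge among ten) recovers reliably.
* **Permutation-stream convention.** Permutation b's shuffle is tied to
  the stored subject order; reordering subjects changes the permuted
  pairings (and hence p-values slightly) while observed betas and all
  designs are exactly invariant.
* **rbf back-projection** is a linearization; only the linear kernel's
  beta map is exactly the fitted model's weight vector.
* The SVR hyperparameters of the original analyses are not public;
  defaults here (linear, C = 1, epsilon = 0.1) are documented package
  decisions, configurable per run, not reconstructions.
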