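# Methods

This note records the modeling choices in `radsurv`, the reasoning behind
the ones that were genuinely open, and the limits of what the synthetic
validation can show.

## Feature extraction

**Discretization.** Intensities inside each ROI are mapped to `n_levels`
(default 64) grey levels by relative min–max resampling:
`level(x) = min(N, floor(N·(x − min)/(max − min)) + 1)`, with a uniform ROI
mapping entirely to level 1. Relative resampling makes every
discretization-based feature invariant to strictly increasing affine
transforms of the raw intensities, which is the appropriate normalization
when cohorts mix scanners and field strengths with arbitrary intensity
scales. The raw-scale first-order statistics (min, max, mean, SD) are
deliberately *not* invariant — they carry the within-ROI contrast signal.

**Catalogue.** The 12 first-order features are 8 histogram statistics
(min, max, mean, population SD, skewness, non-excess kurtosis, base-2
entropy and uniformity of the 64-level histogram) and 4 shape descriptors
(voxel count; volume in ml; sphericity `π^{1/3}(6V)^{2/3}/A`; compacity
`A^{3/2}/V`), with the surface area `A` (mm²) obtained by exposed-voxel-face
counting scaled by the per-axis spacings. Face counting overestimates the
area of smooth shapes relative to a meshed surface; it is used consistently,
so ordering comparisons (e.g. ball vs. slab) are preserved.

**Texture matrices.** All four families are computed in 3D: co-occurrences
and runs over the 13 unique lattice directions at Chebyshev distance 1,
zones and difference neighbourhoods with 26-connectivity. Counts are pooled
over directions into a single matrix before indices are computed (rather
than averaging per-direction indices). GLCM distance is fixed at 1 voxel.
Voxels may be anisotropic (default 5 × 1 × 1 mm, thick axial slices) and
are used as-is: lattice directions are not renormalized by physical
distance, and no resampling to an isotropic grid is performed. Run and
zone percentages are normalized so they lie in (0, 1]: RP divides the run
count by (directions × in-ROI voxels), ZP divides the zone count by the
in-ROI voxel count.

**Degenerate values.** Undefined quantities are NaN, never zero: GLCM
correlation of a uniform ROI, skewness/kurtosis of a single-voxel or
zero-variance ROI, NGLDM contrast/busyness with a single grey level.
NGLDM coarseness carries an additive guard ε = 10⁻⁶ in its denominator so
the uniform-ROI limit is the finite, documented value 1/ε. Downstream,
features missing in more than 20% of training patients are dropped and the
remainder median-imputed with training medians; silent zeros would distort
the rank correlations that drive clustering.

**Correctness.** Every matrix builder is checked against an independent
brute-force enumeration (explicit direction loops, line walking,
flood-fill, explicit neighbourhoods) on random 4×4×4 ROIs, and the whole
catalogue is checked for invariance under axis permutation and affine
intensity transforms.

## Clustering and reduction

Features are clustered on the training split only, with distance
1 − |Spearman ρ|, average linkage, and a tree cut at 1 − 0.90. Absolute
correlation is used because anticorrelated features are legitimately
redundant once members negatively correlated with the cluster anchor are
inverted before averaging. Members are z-scored (training statistics)
before averaging: the features mix incomparable units (entropy, ml,
dimensionless indices), and raw averaging would be dominated by magnitude.
The anchor is the member with the highest mean |ρ| to the others (ties
lexicographic); singletons pass through on their original scale.

A single cluster-and-average pass does not guarantee the advertised
post-condition — the averaged representatives are new columns whose mutual
correlations were never clustered, and in practice a pass can leave pairs
slightly above the threshold. The canonical reduction therefore repeats
the pass on its own output until no representative pair exceeds the
threshold. Convergence is guaranteed (any violating pair is merged by the
next pass, strictly shrinking the table; 2–3 passes in practice), the
fitted per-pass maps are replayed frozen on validation data, and the
reduction is idempotent at its fixed point.

## Feature selection

Each of `n_boot` (default 100) bootstrap resamples of the training split
is ranked by three penalized proportional-hazards fits — ridge, lasso and
elastic-net (mixing 0.5) — with the penalty strength chosen by internal
cross-validation (default 5-fold) of the held-out Breslow log partial
likelihood. Features are ordered by decreasing |standardized coefficient|;
for the sparse penalties, zeroed features rank below all nonzero ones, and
a per-resample list is truncated to the nonzero support (standard
stability-selection convention), so it may be shorter than `top_k`.
Resamples without at least two events are redrawn. All collected lists
(three per resample) are pooled and aggregated by the simple-ensemble
rule: a feature's consensus score is its mean rank with absent features
assigned rank `top_k + 1`; ties break lexicographically, making the whole
procedure deterministic given the seed. The lasso/elastic-net penalty path
uses 50 log-spaced values (fitted in one pass); the ridge grid uses 8
log-spaced values over 10⁻²–10³, because ridge shrinkage is close to
proportional and the coefficient *ordering* — the only thing the ranking
consumes — is nearly invariant to the penalty strength, while a dense
ridge grid would multiply the bootstrap cost several-fold.

How many consensus features feed the forest is a free parameter; the
default is `top_k = 10`, mirroring the per-resample list length.

## Survival modeling

One random survival forest per endpoint and per feature source (tumor
features, node features) — 8 models per run. Trees split by the log-rank
statistic; the predicted risk is the ensemble mortality (sum of the
ensemble cumulative hazard over the event-time grid), so risk is a
unitless ranking score. Defaults: 1000 trees; grid over
mtry ∈ {√p, p/3, p} and minimum node size ∈ {3, 6, 15}; 5-fold CV
stratified by the event indicator, scored by out-of-fold Harrell C-index;
grid ties resolve to the first point in deterministic grid order. A
folding that leaves a training fold without events is redrawn with an
incremented seed.

## Evaluation

* **Harrell's C** — pairs comparable iff the strictly smaller time is an
  observed event; risk ties count ½; pairs with exactly tied times are not
  comparable. No comparable pairs → NaN with a warning.
* **Time-dependent AUC** — the cumulative/dynamic estimator at 36 months
  with Kaplan–Meier IPCW (several estimators exist in the literature; this
  choice is isolated behind one function). With no censoring it reduces
  exactly to the binary AUC of (event by 36 months) vs. risk.
* **Cutpoint** — candidates are the observed risk values leaving at least
  10% of patients on each side (a configurable guard against degenerate
  groups); the scan maximizes the two-group log-rank statistic; statistic
  ties resolve to the lower cutoff. The cutpoint is derived on training
  risks and applied frozen to validation (re-deriving it on validation
  would leak the validation outcomes into the grouping).
* **Proportional-hazards tables** — univariate and joint multivariate fits
  (Efron tie handling via lifelines); exactly collinear covariates are
  rejected; monotone-likelihood separation (|log HR| > 15 or a non-finite/
  huge standard error) is flagged `unstable` with NaN estimates instead of
  a meaningless number.

## Synthetic cohorts

The generator emulates the study conditions end to end: 93 patients by
default, two sequences with different structure mean intensities, one
tumor and one node ROI per patient (ellipsoids, default radii 12–22 mm and
6–11 mm on a 20×96×64 grid at 5×1×1 mm), per-patient latent texture
parameters (Gaussian-field correlation length 0.5–2.5 voxels; contrast
0.5–3, i.e. an in-ROI SD of 5–30 intensity units), and survival times from
a proportional-hazards model on the standardized latents with an
exponential baseline (scale 60 months; a Weibull shape parameter is
available and recorded on the cohort specification). Censoring is one administrative uniform censoring
time per patient, with the horizon calibrated numerically so the expected
censored fraction matches the requested rate (default 0.3, a plausible
follow-up maturity for such cohorts). The default coupling sends tumor
latents to LC and node latents to RC/DMFS/OS with coefficient 0.7 per
standardized latent — a hazard ratio of exp(0.7·√12/2) ≈ 3.4 across a
latent's interquartile range — so the qualitative finding the pipeline
should recover (tumor features predict LC better, node features predict
RC/DMFS/OS better) is true by construction. All randomness flows from one
seed through a child stream per patient, so cohorts are bit-reproducible
and patient *i* is identical in cohorts of different sizes.

What the generator does **not** emulate: MR physics (bias fields, motion,
coil profiles), inter-observer segmentation variability, multi-node
anatomy, correlated censoring, non-proportional hazards, and any realistic
relationship between tumor biology and texture. Passing tests therefore
demonstrate that the pipeline is *correct and able to recover a known
signal of realistic strength* — not that the features are prognostic in
real patients.

## Problem sizes in the test suite

The validation suite favors many moderate simulations over few large
ones: the recovery experiment runs the full image-to-report pipeline on
ten 93-patient cohorts with 5 bootstrap resamples, a 200-tree forest and
a single-point hyperparameter grid; the null calibrations use 20–50
replicates (tabular cohorts of 80–500 patients) and 1000 small-sample
log-rank replicates; matrix oracles run on twenty 4×4×4 ROIs. The
acceptance script uses 50 patients (perfect ranking), 50×500 patients
(null C-index) and one 93-patient cohort (reduction audit).

## Known limitations

* The within-cohort bootstrap selection frequencies of pure-noise features
  are *not* bounded by the idealized binomial envelope: resamples of one
  realized cohort are mutually correlated, so the feature with the largest
  chance association is re-selected far more often than independent
  binomial draws would predict, and this does not vanish with cohort size
  (both the chance association and the selection threshold scale as
  1/√n). Bootstrap selection frequencies should be read as *relative*
  stability evidence, not as calibrated error rates; calibrated guarantees
  would require complementary-pairs stability selection, which is out of
  scope.
* C-index and time-dependent AUC are reported without confidence
  intervals; dispersion across seeds/folds is available from the tuning
  table and replicate runs.
* Fitted forests are persisted as manifests (features, hyperparameters,
  seed) plus predictions, not as serialized estimator objects; a model is
  re-fitted from its manifest when needed, which is exact because fitting
  is deterministic given the manifest and data.
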