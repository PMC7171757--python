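# radsurv

Radiomic texture analysis and survival-forest outcome modeling for
dual-sequence MR imaging of tumors and involved lymph nodes.

## The problem

In node-positive cervical cancer treated with definitive chemoradiotherapy,
outcomes vary widely under a nearly uniform treatment. Quantitative imaging
features of the primary tumor and the largest involved lymph node —
histogram, shape and 3D texture descriptors computed from pre-treatment
contrast-enhanced T1-weighted and T2-weighted MR — carry prognostic
information about four time-to-event endpoints: local control (LC),
regional control (RC), distant metastasis-free survival (DMFS) and overall
survival (OS). `radsurv` implements the full analysis pipeline for this
setting, for imaging scientists and biostatisticians who want a tested,
reproducible reference implementation:

1. **Feature extraction** — per ROI and sequence, 43 features: 12
   first-order (8 histogram statistics + 4 shape descriptors), 6 grey-level
   co-occurrence matrix (GLCM), 11 run-length (GLRLM), 3 neighbourhood
   grey-level difference (NGLDM) and 11 zone-length (GLZLM) features, all
   texture matrices accumulated in 3D over 13 lattice directions /
   26-connectivity, on intensities discretized to 64 levels by relative
   min–max resampling within the ROI (86 features per structure over the
   two sequences).
2. **Feature clustering** — features with |Spearman ρ| > 0.90 are grouped
   by hierarchical clustering (distance 1 − |ρ|, average linkage) and each
   cluster replaced by the mean of its sign-aligned, z-scored members,
   iterated until no representative pair exceeds the threshold.
3. **Feature selection** — ridge-, lasso- and elastic-net-penalized Cox
   models ranked on 100 bootstrap resamples of the training split; the
   per-resample top-10 lists are combined by simple-ensemble rank
   aggregation (mean rank, absent → rank 11).
4. **Outcome modeling** — a random survival forest (log-rank splitting,
   ensemble-mortality risk) per endpoint and per feature source (tumor vs.
   node), with grid-search hyperparameter tuning under event-stratified
   cross-validation.
5. **Evaluation** — Harrell's C-index, 3-year (36-month) cumulative/dynamic
   AUC with Kaplan–Meier censoring weights, maximally-selected log-rank
   risk cutpoint derived on training and applied frozen to validation,
   Kaplan–Meier curves, log-rank tests, and proportional-hazards tables
   for the dichotomized risk score.

Because clinical MR cohorts of this kind are not public, the package ships
a first-class **synthetic cohort generator**: ellipsoidal tumor/node ROIs
with Gaussian-random-field texture whose latent parameters (correlation
length, contrast) drive a proportional-hazards survival model with
independent administrative censoring. By default the tumor latents drive
LC and the node latents drive RC/DMFS/OS, so the pipeline's ability to
recover a known source-specific signal is testable end to end.

## Core quantities

For risks $r_i$ and right-censored outcomes $(t_i, \delta_i)$, Harrell's
concordance is

$$C = \frac{\sum_{i,j} \mathbf{1}[t_i < t_j,\ \delta_i = 1]\,
      (\mathbf{1}[r_i > r_j] + \tfrac12 \mathbf{1}[r_i = r_j])}
     {\sum_{i,j} \mathbf{1}[t_i < t_j,\ \delta_i = 1]},$$

with $C = 0.5$ for a random and $C = 1$ for a perfect prediction. The
3-year discrimination is the cumulative/dynamic AUC at $t = 36$ months
with inverse-probability-of-censoring weights from the Kaplan–Meier
estimate of the censoring distribution. Texture indices follow the
standard Galloway/Chu (GLRLM), Amadasun–King (NGLDM) and zone-length
(GLZLM) definitions on matrices pooled over all 3D directions.

## Worked example

Run the whole pipeline on a 93-patient synthetic cohort (62/31
train/validation split), with a reduced bootstrap count and forest size
for a quick desk-scale run:

```python
from radsurv.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    cohort={"n_patients": 93},
    n_boot=5, top_k=10, rsf_n_estimators=200,
    rsf_grid={"max_features": ("sqrt",), "min_samples_leaf": (6,)},
    cv_folds=3, seed=0, out_dir="runs")
reports = run_pipeline(cfg)["reports"]
```

Printing validation metrics per model (`<structure>_<endpoint>`) gives:

```
model        C-index (val)  AUC@36mo  log-rank p
node_DMFS            0.759     0.795       0.005
node_LC              0.473     0.454       0.172
node_OS              0.621     0.634       0.475
node_RC              0.754     0.825       0.002
tumor_DMFS           0.497     0.506       0.941
tumor_LC             0.665     0.724       0.157
tumor_OS             0.491     0.572       0.922
tumor_RC             0.588     0.648       0.780
```

The construction is recovered: tumor-feature models discriminate LC best
(0.665 vs 0.473), node-feature models discriminate RC/DMFS/OS best, and
the node-based RC/DMFS risk groups separate significantly by log-rank.
The run directory contains the feature table, cluster maps, per-model
selection lists, tuning scores, predicted risks and a manifest; re-running
the same configuration reproduces every number bit-identically.

The same pipeline is available from the shell:

```sh
radsurv simulate --n-patients 93 --seed 0 --out cohort/
radsurv extract --data-dir cohort/ --out features.csv
radsurv run-all --seed 0 --out runs/
```

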