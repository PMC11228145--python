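# Methods

This note documents the models and procedures implemented in `glucotab`,
the defaults that matter, the synthetic data the package is validated on,
and the numerical and design choices made where the design was open.

## Data model

A clinical table is a patient × attribute matrix over a declared schema of
39 predictor columns — age and gender (group A) plus 37 numeric medical-test
indicators in six functional groups (B liver function, C kidney function,
D lipid profile, E hepatitis-B markers, F complete blood count, G white-cell
differential) — and a continuous blood-glucose target. Missingness is an
explicit boolean mask; unobserved cells hold NaN and are never read by
numerics. On disk, tables are plain CSV with empty fields for missing cells
(`NA`/`NaN` tokens also accepted); gender is coded male → 1, female → 0 and
may not be missing. The target's physical units are not modelled; it is
treated as a unitless continuous value.

## Cluster-informed stepwise imputation

Patients are clustered with DBSCAN on the 19 near-complete attributes
(A1, A2, F1–F12, G1–G5). Cells missing inside the clustering features are
filled with the column median, columns are z-scored, and `eps` defaults to
the k-distance heuristic (90th percentile of k-NN distances, k =
`min_samples` = 10). Noise points keep a dedicated label. Cluster-level
means over *originally observed* cells (global means as fallback, also for
noise points) supply *m* = 20 auxiliary features, one per panel attribute
(B1…E5).

Missing columns are filled in schema order within groups B, C, D, E,
starting at B1 (an ascending-missing-count order is available). For each
attribute a LightGBM regressor (200 trees, 31 leaves, learning rate 0.05,
subsample 0.8, seeded, single-threaded) is fit on the patients observing it
with predictors = 19 clustering features ∪ 20 auxiliary columns ∪ all
previously completed columns, and predicts the missing entries. Observed
cells are never altered; every filled cell carries an `imputed` provenance
flag. Cell-level gaps inside the clustering features receive their median
fill in the output so the completed table has no open predictor cells. The
auxiliary columns are used only as imputation predictors and are dropped
afterwards; they are computed once from the original observed data (a
recompute-per-cycle variant was considered and rejected as an unneeded
second pass — the auxiliary values do not depend on the filled panels).

The baseline the stepwise strategy is measured against is the column-mean
(numeric) / column-mode (categorical) fill.

## Dual-layer augmentation

**Sample augmentation.** For each patient, 2 perturbed copies are appended
to the *training split only*. Each copy shifts `n_perturb` = 10 distinct
indicator features (numeric, excluding age/gender and appended `_grp`
columns) by Δ_f ~ Uniform(−ε_f, ε_f), with ε_f = `epsilon_ratio` × |training
column mean| and `epsilon_ratio` = 1/20. The uniform law is the
maximum-entropy choice under the stated bound; the absolute value guards
synthetic columns whose means could be negative (clinical analytes are
positive, where it is the plain mean). Imputed cells are eligible for
perturbation (flag to exclude). Targets are copied unchanged.

**Feature augmentation.** A second DBSCAN clustering on *all* numeric
predictor columns (z-scored) appends, for every attribute of the selected
groups (default {B, D}), a `<id>_grp` column holding that attribute's
cluster mean (global mean for noise points): 12 appended columns by
default, 37 when all indicator groups are selected. Each appended block is
registered as a new schema group (`B_grp`, `D_grp`) and forms one
additional mask unit.

## Group-masked attentive network

The regressor is a sequential attentive tabular architecture (TabNet
family) operating on batch-normalised inputs, with gender entering through
a learned scalar embedding. Its atomic attention object is the *mask unit*:
by default the liver-function group B is one unit, the lipid-profile group
D is one unit, each `_grp` block is one unit, and every remaining column is
a singleton. With an all-singleton partition the model reduces exactly to
standard per-feature masking (verified against an independently written
reference forward pass in the tests).

Per decision step *i* (defaults: `n_steps` desk-scale 3, library default 4):

- scores = ghost-batch-normalised affine map of the previous attention
  representation to unit dimension;
- attention q[i] = projection of P[i−1] ⊙ scores onto the capped simplex
  {0 ≤ q ≤ min(P[i−1], 1), Σq = 1}, computed by bisection on the clip
  threshold (80 iterations, |Σq − 1| ≲ 1e−12). Whenever no cap binds —
  in particular at step 0, where P = 1 — this is exactly sparsemax.
  The cap is the deliberate design choice here: plain sparsemax of
  prior-scaled scores cannot guarantee that an already-attended unit is not
  re-selected (a unit attended at weight 0.5 could later receive weight 1),
  whereas capping attention by the remaining prior provably yields the
  telescoping budget Σ_i q[i] ≤ 1 per unit at relaxation γ = 1. Rows whose
  caps sum below 1 (only possible when nearly all units are exhausted) fall
  back to the normalised caps. Backward pass: the exact Jacobian-vector
  product on the free support; coordinates pinned at 0 or at their cap get
  no gradient and the caps are treated as constants.
- feature mask M[i] = q[i]·G (each member column carries the unit's value;
  a mass-splitting mode q/|unit| is available), applied multiplicatively to
  the normalised input;
- feature transformer: 2 shared + 2 step-specific GLU blocks (affine to
  double width → ghost batch norm → gated linear unit), residuals scaled by
  √½; the output splits into a decision part (width `n_d`) and the next
  attention representation (width `n_a`);
- prior update P[i] = P[i−1] ⊙ (γ·1 − q[i]), P[0] = 1, γ = 1.5 by default.

The prediction is an affine map of the summed rectified decisions. The
sparsity regulariser is the mean entropy Σ −q log(q + 1e−15), weighted by
λ_sparse = 1e−4. Aggregate importance M_agg ∝ Σ_i η_b[i]·M[i] with
η_b[i] = Σ channels of the rectified decision, row-normalised (rows with no
active decision fall back to uniform); per-unit importance is the mean
M_agg mass summed over the unit's member columns.

Training: Adam (lr 2e−2, ×0.9 every 10 epochs), batch 256, ghost batches of
128 (batch-norm running statistics updated with momentum 0.1 and frozen for
inference), MSE + sparsity loss, early stopping on validation MSE with the
peak-validation parameters restored. All randomness (initialisation,
shuffling) derives from the config seed; two runs with the same seed
produce identical training logs. The network and its reverse-mode autodiff
core are implemented in NumPy inside the package.

## Pipeline, ablations, robustness

Order: impute → feature-augment → split 80/10/10 → sample-augment (train
only) → fit → evaluate, with a master seed fanned out to per-stage seeds by
a fixed rule. Imputation and clustering are fit on the full table before
splitting, as the staged design implies; a strict mode processes each split
independently for leakage-sensitive use. Ablation switches replace stepwise
imputation by mean fill (−Imp), drop the perturbed copies (−AugS), drop the
`_grp` columns (−AugF), or use all-singleton masking (−GM); with all four
off the pipeline is the standard per-feature attentive network on
mean-filled data. Flags touch only their stage: upstream stage outputs hash
identically across arms sharing a seed.

Metrics: MAE = n⁻¹Σ|y−ŷ|, MSE = n⁻¹Σ(y−ŷ)², RMSE = √MSE. The robustness
protocol perturbs every test row on 10 random continuous features with the
training-mean ε_f, repeats 20 times (seeded), and reports mean metric
deltas (perturbed − base).

## Synthetic data

The generator emulates the structure the framework assumes, not the
marginals of real analytes. Per patient: a latent cluster (K = 3 default)
drawn uniformly; indicator columns are cluster mean + unit-variance
Gaussian noise, with cluster means = a positive per-column baseline
(Uniform(5, 50), drawn once per seed) plus a Normal(0, `cluster_sep`)
offset; age is a truncated normal, gender Bernoulli(½), both
cluster-independent (demographics are clustering features, not signal).
The target is y = 5.5 + Σ coef_j·(x_j − baseline_j) + Normal(0, noise_sd)
with nonzero coefficients (Normal(0, `coef_scale`)) only on the signal
groups (default {B, D}): blood glucose responds to deviations from
reference levels, which keeps the target near its fasting-glucose-like
intercept instead of inheriting a large constant offset from the baselines.
Missingness is missing-at-random by design: each panel group B–E is dropped
wholesale per patient with `group_missing_prob` (0.3 default), then
indicator cells drop out with `cell_missing_prob` (0.02); demographics stay
complete and F/G see cell-level dropout only, mirroring a near-complete
blood count. The positive baselines are what make the mean-proportional
perturbation half-width ε_f = mean/20 meaningful, as it is for real
positive-valued analytes.

What passing tests on these tables do and do not show: they validate the
mechanisms (cluster information improves imputation where clusters differ;
group masking finds planted group-level signal; perturbation training
reduces perturbation sensitivity) under conditions where the assumptions
hold exactly. They do not certify performance on real clinical data, whose
clusters are fuzzier, whose missingness may be informative, and whose
analyte distributions are skewed.

## Desk-scale study conditions

The reference studies (tests and `scripts/acceptance.py`) use sizes chosen
for a single CPU: imputation recovery on n = 2,000 patients; the paired
pipeline study on n = 1,500 per seed, five shared seeds, with a network of
3 steps, widths n_d = n_a = 8, up to 60 epochs (patience 15); robustness
deltas averaged over 20 perturbation repeats. Simulation conditions:
cluster_sep = 3, group_missing_prob = 0.3, cell_missing_prob = 0.02,
coef_scale = 1, noise_sd = 1.

## Known limitations

- Single imputation only; no uncertainty propagation through the fill.
- DBSCAN's eps heuristic can declare sparse patients noise; they fall back
  to global means for all cluster-level quantities.
- The capped-simplex attention treats caps as constants in the backward
  pass, so no gradient flows into the prior through the cap (only through
  the prior-scaled scores); this is a deliberate, documented approximation.
- One row per patient; no longitudinal records.
- CPU-only by design; the autodiff core favours clarity over speed and is
  sized for tables of a few thousand rows.
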