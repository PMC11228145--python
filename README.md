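# glucotab

Group-informed attentive modelling of blood-glucose progression from routine
clinical tables.

Clinical examination data come with structure that generic tabular models
ignore: the 37 medical-test indicators of a standard panel fall into six
functional groups (liver function tests, kidney function tests, lipid
profile, hepatitis-B markers, complete blood count, white-cell
differential), patients skip whole panels at a time (so missingness is
group-structured), and patients themselves form latent clusters with
correlated physiology. `glucotab` implements a regression framework for
predicting blood-glucose concentration that exploits all three facts:

1. **Cluster-informed stepwise imputation.** Patients are clustered with
   DBSCAN on the 19 near-complete attributes (age, gender, CBC,
   differential); each cluster contributes *m* = 20 cluster-level mean
   features for the panel attributes (B1–E5). Missing columns are then
   filled one at a time with gradient-boosted tree regressors — starting at
   B1 — each completed column feeding the next prediction cycle.
2. **Dual-layer augmentation.** Sample level: each patient contributes two
   perturbed copies, with *n* = 10 randomly chosen indicator features
   shifted by Δ_f drawn uniformly from (−ε_f, ε_f), where
   ε_f = (column mean)/20. Feature level: a second, all-feature DBSCAN
   clustering appends group-level mean columns (`B1_grp` … `D4_grp`, 12
   columns for the default groups B and D) to every patient.
3. **A group-masked attentive tabular network.** A multi-step attentive
   architecture in the TabNet family, where the attentive transformer
   selects over *mask units*: the liver-function and lipid-profile groups
   each share a single attention value (a group gets one mask), everything
   else is a singleton. Attention at step *i* is the projection of
   P[i−1]·scores onto the capped simplex {0 ≤ q ≤ min(P, 1), Σq = 1} — plain
   sparsemax whenever no cap binds — with prior update
   P[i] = P[i−1]·(γ − q[i]). Per-step masks M[i] = q[i]·G broadcast unit
   attention to member columns, and the aggregate importance M_agg is the
   η-weighted, row-normalised sum of the M[i], where η_b[i] is the step's
   total rectified decision magnitude.

The model is trained with Adam on MSE plus a sparsity penalty
λ·Σ −q log q, with peak-validation model selection on an 80/10/10 split,
and is evaluated with MAE, MSE and RMSE. Ablation switches disable each
stage independently (mean-fill instead of stepwise imputation, no perturbed
copies, no `_grp` columns, all-singleton masking), and a robustness protocol
re-applies the bounded perturbation to test rows and reports metric deltas.

The network, its attention projections and the automatic differentiation
core are implemented in NumPy within this package (`glucotab.autodiff`,
`glucotab.network`); clustering and the boosted imputation regressors use
scikit-learn and LightGBM.

## Worked example

```python
import numpy as np
from glucotab import (SimulationConfig, simulate_table, cluster_patients,
                      plan_imputation, impute_stepwise, mean_fill_baseline,
                      missingness_summary)

table, truth = simulate_table(SimulationConfig(n_patients=800, seed=7))
summary = missingness_summary(table)
print("missing cells:", summary["total_missing"])
print("whole-panel gaps:", summary["per_group_all_missing"])

model = cluster_patients(table)
print("clusters found:", len(model.cluster_ids),
      "noise points:", int((model.labels == -1).sum()))

plan = plan_imputation(table, model, seed=7)
completed = impute_stepwise(table, plan, model)
masked = ~table.observed
truth_vals = truth["complete_values"][masked]
rmse = lambda t: float(np.sqrt(np.mean((t.values[masked] - truth_vals) ** 2)))
print(f"stepwise imputation RMSE: {rmse(completed):.3f}")
print(f"column-mean fill RMSE:    {rmse(mean_fill_baseline(table)):.3f}")
```

prints

```
missing cells: 5036
whole-panel gaps: {'A': 0, 'B': 233, 'C': 215, 'D': 237, 'E': 214, 'F': 0, 'G': 0}
clusters found: 3 noise points: 4
stepwise imputation RMSE: 1.196
column-mean fill RMSE:    2.436
```

Roughly 30% of the 800 simulated patients skip each panel (B–E) outright;
density clustering recovers the three latent patient groups, and feeding
cluster-level information into the stepwise fill roughly halves the
imputation RMSE relative to the column-mean baseline.

The same flow is available from the shell:

```sh
glucotab simulate --n 800 --seed 7 --out table.csv
glucotab impute --table table.csv --out completed.csv --report impute.json
glucotab train --table table.csv --out-prefix run/model
glucotab robustness --model run/model --table completed.csv \
    --means-json run/model.manifest.json
```

`glucotab train` prints the held-out test metrics of the peak-validation
model and exports per-unit importances; `glucotab ablation` writes the
metric files for the full model and the four single-component removal
variants.

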