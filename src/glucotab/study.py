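"""Desk-scale simulation studies exercising the full framework.

These are the package's reference experiments on synthetic tables: the
imputation-recovery comparison (stepwise cluster-informed fill vs column
means, scored against the pre-masking ground truth) and the paired ablation
/ robustness study (full pipeline vs variants over shared simulation seeds).
Problem sizes are chosen for a single desk CPU; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .augment import PerturbSpec
from .clustering import cluster_patients
from .impute import impute_stepwise, mean_fill_baseline, plan_imputation
from .network import TabNetConfig
from .pipeline import PipelineConfig, robustness_eval, run_pipeline
from .simulate import SimulationConfig, simulate_table

#: simulation conditions for the pipeline studies
STUDY_SIM = SimulationConfig(
    n_patients=1500,
    n_clusters=3,
    cluster_sep=3.0,
    signal_groups=("B", "D"),
    coef_scale=1.0,
    noise_sd=1.0,
    group_missing_prob=0.3,
    cell_missing_prob=0.02,
)

#: simulation conditions for the imputation-recovery study
IMPUTE_SIM = replace(STUDY_SIM, n_patients=2000)


def desk_tabnet_config(seed: int = 0) -> TabNetConfig:
    """Network scaled to the ~1.5k-row synthetic tables of the studies."""
    return TabNetConfig(
        n_steps=3, n_d=8, n_a=8, gamma=1.5, lambda_sparse=1e-4,
        n_shared=2, n_independent=2, virtual_batch=128, batch=256,
        lr=2e-2, max_epochs=60, patience=15, seed=seed,
    )


def desk_pipeline_config(seed: int = 0, **flags) -> PipelineConfig:
    return PipelineConfig(tabnet=desk_tabnet_config(), seed=seed, **flags)


STANDARD_ARM = dict(
    enable_imputation=False,
    enable_sample_aug=False,
    enable_feature_aug=False,
    enable_group_mask=False,
)


def imputation_recovery_study(seed: int = 0) -> dict:
    """RMSE of stepwise vs mean-fill imputation on the same masked cells,
    measured against the pre-masking matrix of a cluster-structured table."""
    table, truth = simulate_table(replace(IMPUTE_SIM, seed=seed))
    masked = ~table.observed
    cm = cluster_patients(table)
    plan = plan_imputation(table, cm, seed=seed)
    stepwise = impute_stepwise(table, plan, cm)
    meanfill = mean_fill_baseline(table)

    truth_vals = truth["complete_values"][masked]

    def rmse(completed):
        return float(np.sqrt(np.mean((completed.values[masked] - truth_vals) ** 2)))

    return {
        "n_masked_cells": int(masked.sum()),
        "n_patients": table.n_patients,
        "rmse_stepwise": rmse(stepwise),
        "rmse_mean_fill": rmse(meanfill),
        "observed_unchanged": bool(
            np.array_equal(
                stepwise.values[table.observed], table.values[table.observed]
            )
        ),
    }


def signal_unit_mass(unit_importance: dict[str, float],
                     signal_groups=("B", "D")) -> float:
    """Aggregate-importance mass on the units covering the signal groups
    (the clinical groups themselves, their member singletons when unmasked,
    and their appended ``_grp`` blocks)."""
    keys = set(signal_groups) | {f"{g}_grp" for g in signal_groups}
    mass = 0.0
    for uid, value in unit_importance.items():
        if uid in keys or any(uid.startswith(g) for g in signal_groups):
            mass += value
    return mass


def paired_pipeline_study(
    seeds: list[int],
    arms: dict[str, dict] | None = None,
    robustness_arms: tuple[str, ...] = ("full", "-AugS"),
    robustness_repeats: int = 20,
) -> dict:
    """Run the pipeline arms on shared simulated tables, one table per seed.

    Default arms: the full model, the no-sample-augmentation variant, and
    the all-components-off standard per-feature baseline.  Robustness deltas
    (perturbed minus base test metrics) are evaluated for ``robustness_arms``
    with epsilon taken from each run's training means.
    """
    if arms is None:
        arms = {
            "full": {},
            "-AugS": {"enable_sample_aug": False},
            "standard": dict(STANDARD_ARM),
        }
    records = []
    for seed in seeds:
        table, _ = simulate_table(replace(STUDY_SIM, seed=seed))
        rec: dict = {"seed": seed, "arms": {}}
        for name, overrides in arms.items():
            result = run_pipeline(table, desk_pipeline_config(seed=seed, **overrides))
            arm_rec = {
                "metrics": result.metrics.as_dict(),
                "signal_mass": signal_unit_mass(result.unit_importance),
            }
            if name in robustness_arms:
                spec = PerturbSpec(
                    column_means=result.train_means,
                    seed=result.manifest["seeds"]["robustness"],
                )
                _, _, deltas = robustness_eval(
                    result.model, result.test_table, spec,
                    repeats=robustness_repeats,
                )
                arm_rec["robustness_deltas"] = deltas
            rec["arms"][name] = arm_rec
        records.append(rec)

    def mean_over(path):
        vals = []
        for rec in records:
            node = rec["arms"]
            for key in path:
                node = node[key]
            vals.append(node)
        return float(np.mean(vals))

    summary = {
        "n_patients": STUDY_SIM.n_patients,
        "seeds": list(seeds),
        "mean_test_mse": {a: mean_over((a, "metrics", "mse")) for a in arms},
        "mean_test_mae": {a: mean_over((a, "metrics", "mae")) for a in arms},
        "mean_test_rmse": {a: mean_over((a, "metrics", "rmse")) for a in arms},
        "mean_signal_mass": {a: mean_over((a, "signal_mass")) for a in arms},
    }
    for metric in ("mae", "mse", "rmse"):
        summary[f"mean_robustness_delta_{metric}"] = {
            a: mean_over((a, "robustness_deltas", metric))
            for a in robustness_arms if a in arms
        }
    return {"records": records, "summary": summary}
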