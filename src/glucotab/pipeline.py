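"""End-to-end pipeline: impute -> group-feature augment -> split -> sample
augment -> fit -> evaluate, plus the ablation arms and the robustness
protocol (bounded perturbation of test rows, metric deltas)."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .augment import (
    GroupAugmentSpec,
    PerturbSpec,
    _perturb_rows,
    augment_group_features,
    augment_samples,
    eligible_perturb_features,
    perturbation_halfwidths,
)
from .clustering import cluster_patients
from .errors import DataError, ParameterError
from .impute import impute_stepwise, mean_fill_baseline, plan_imputation
from .network import GroupMaskedTabNet, MaskUnitPartition, TabNetConfig
from .schema import ClinicalTable


@dataclass(frozen=True)
class Metrics:
    mae: float
    mse: float
    rmse: float
    n: int

    def as_dict(self) -> dict:
        return {"mae": self.mae, "mse": self.mse, "rmse": self.rmse, "n": self.n}


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> Metrics:
    """MAE = mean |y - yhat|, MSE = mean (y - yhat)^2, RMSE = sqrt(MSE)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise DataError("metric inputs must be equal-length vectors")
    if len(y) == 0:
        raise DataError("metric inputs are empty")
    err = y - yhat
    mse = float(np.mean(err ** 2))
    return Metrics(
        mae=float(np.mean(np.abs(err))),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        n=len(y),
    )


def split_table(
    table: ClinicalTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[ClinicalTable, ClinicalTable, ClinicalTable]:
    """Seed-reproducible random disjoint train/valid/test partition."""
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ParameterError("three positive split fractions required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError("split fractions must sum to 1")
    n = table.n_patients
    n_valid = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_valid - n_test
    if min(n_train, n_valid, n_test) < 1:
        raise DataError("a split would be smaller than one row")
    perm = np.random.default_rng(seed).permutation(n)
    return (
        table.take(perm[:n_train]),
        table.take(perm[n_train:n_train + n_valid]),
        table.take(perm[n_train + n_valid:]),
    )


@dataclass
class PipelineConfig:
    enable_imputation: bool = True
    enable_sample_aug: bool = True
    enable_feature_aug: bool = True
    enable_group_mask: bool = True
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    masked_groups: tuple[str, ...] = ("B", "D")
    augment_groups: tuple[str, ...] = ("B", "D")
    n_perturb: int = 10
    epsilon_ratio: float = 1.0 / 20.0
    copies_per_patient: int = 2
    cluster_min_samples: int = 10
    imputation_params: dict | None = None
    tabnet: TabNetConfig = field(default_factory=TabNetConfig)
    strict_split_fit: bool = False
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Master seed fanned out to stage seeds via a fixed splitting rule."""
        ss = np.random.SeedSequence(self.seed)
        names = ("imputation", "split", "sample_aug", "network", "robustness")
        states = ss.generate_state(len(names))
        return {name: int(s % (2**31 - 1)) for name, s in zip(names, states)}


@dataclass
class PipelineResult:
    metrics: Metrics
    model: GroupMaskedTabNet
    unit_importance: dict[str, float]
    aggregate_importance: np.ndarray
    test_table: ClinicalTable
    train_means: dict[str, float]
    manifest: dict


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _complete(table: ClinicalTable, config: PipelineConfig, seed: int) -> ClinicalTable:
    if not config.enable_imputation:
        return mean_fill_baseline(table)
    if table.is_complete:
        return table
    cm = cluster_patients(table, min_samples=config.cluster_min_samples)
    plan = plan_imputation(table, cm, model_params=config.imputation_params, seed=seed)
    return impute_stepwise(table, plan, cm)


def run_pipeline(table: ClinicalTable, config: PipelineConfig) -> PipelineResult:
    """Execute the staged pipeline under the ablation flags.

    Disabled imputation falls back to column-mean fill; disabled feature
    augmentation appends no ``_grp`` columns; disabled sample augmentation
    trains on the unexpanded split; disabled group masking uses an
    all-singleton partition (the standard per-feature attentive network).
    Test metrics come from the peak-validation model.
    """
    if table.target is None:
        raise DataError("pipeline requires a target column")
    seeds = config.stage_seeds()
    manifest: dict = {"seeds": seeds, "flags": {
        "imputation": config.enable_imputation,
        "sample_aug": config.enable_sample_aug,
        "feature_aug": config.enable_feature_aug,
        "group_mask": config.enable_group_mask,
    }}

    if config.strict_split_fit:
        raw_train, raw_valid, raw_test = split_table(table, config.split, seeds["split"])
        completed_splits = [
            _complete(part, config, seeds["imputation"])
            for part in (raw_train, raw_valid, raw_test)
        ]
        if config.enable_feature_aug:
            spec = GroupAugmentSpec(selected_groups=config.augment_groups,
                                    min_samples=config.cluster_min_samples)
            completed_splits = [augment_group_features(p, spec) for p in completed_splits]
        train, valid, test = completed_splits
    else:
        completed = _complete(table, config, seeds["imputation"])
        manifest["imputed_digest"] = _digest(completed.values)
        if config.enable_feature_aug:
            completed = augment_group_features(
                completed,
                GroupAugmentSpec(selected_groups=config.augment_groups,
                                 min_samples=config.cluster_min_samples),
            )
        manifest["feature_aug_digest"] = _digest(completed.values)
        train, valid, test = split_table(completed, config.split, seeds["split"])

    schema = train.schema
    eligible = eligible_perturb_features(schema)
    train_means = {
        a: float(train.column(a).mean()) for a in eligible
    }
    if config.enable_sample_aug:
        spec = PerturbSpec(
            n_perturb=config.n_perturb,
            epsilon_ratio=config.epsilon_ratio,
            copies_per_patient=config.copies_per_patient,
            column_means=train_means,
            seed=seeds["sample_aug"],
        )
        train_fit = augment_samples(train, spec)
    else:
        train_fit = train
    manifest["train_rows"] = train_fit.n_patients

    if config.enable_group_mask:
        partition = MaskUnitPartition.from_schema(schema, config.masked_groups)
    else:
        partition = MaskUnitPartition.singletons(
            schema.n_attributes, schema.attribute_ids
        )
    net_config = replace(config.tabnet, seed=seeds["network"])
    model = GroupMaskedTabNet(schema, partition, net_config)
    model.fit(train_fit, valid)

    yhat = model.predict_table(test)
    metrics = compute_metrics(test.target, yhat)
    trace, unit_importance = model.explain(test.values)
    manifest["test_digest"] = _digest(test.values)
    manifest["epochs_run"] = len(model.training_log)
    return PipelineResult(
        metrics=metrics,
        model=model,
        unit_importance=unit_importance,
        aggregate_importance=trace.aggregate_importance,
        test_table=test,
        train_means=train_means,
        manifest=manifest,
    )


def robustness_eval(
    model: GroupMaskedTabNet,
    test: ClinicalTable,
    spec: PerturbSpec,
    repeats: int = 20,
) -> tuple[Metrics, Metrics, dict[str, float]]:
    """Perturb every test row on ``n_perturb`` random continuous features
    (epsilon from TRAINING means, carried in ``spec.column_means``), evaluate,
    and report mean metric deltas (perturbed - base) across repeats."""
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    if not test.is_complete or test.target is None:
        raise DataError("robustness evaluation needs a complete labelled table")
    eligible = spec.validate(test.schema)
    eps = perturbation_halfwidths(test, spec, eligible)
    eligible_idx = np.array([test.schema.index_of(a) for a in eligible])

    base_pred = model.predict_table(test)
    base = compute_metrics(test.target, base_pred)
    rng = np.random.default_rng(spec.seed)
    perturbed = []
    for _ in range(repeats):
        values, _cells = _perturb_rows(
            test.values, eligible_idx, eps, spec.n_perturb, rng
        )
        perturbed.append(compute_metrics(test.target, model.predict(values)))
    mean_pert = Metrics(
        mae=float(np.mean([m.mae for m in perturbed])),
        mse=float(np.mean([m.mse for m in perturbed])),
        rmse=float(np.mean([m.rmse for m in perturbed])),
        n=base.n,
    )
    deltas = {  # mean of per-repeat differences: exactly 0 when eps = 0
        "mae": float(np.mean([m.mae - base.mae for m in perturbed])),
        "mse": float(np.mean([m.mse - base.mse for m in perturbed])),
        "rmse": float(np.mean([m.rmse - base.rmse for m in perturbed])),
    }
    return base, mean_pert, deltas


ABLATION_ARMS = {
    "full": {},
    "-Imp": {"enable_imputation": False},
    "-AugS": {"enable_sample_aug": False},
    "-AugF": {"enable_feature_aug": False},
    "-GM": {"enable_group_mask": False},
}


def run_ablation(
    table: ClinicalTable, config: PipelineConfig,
    arms: dict[str, dict] | None = None,
) -> dict[str, PipelineResult]:
    """Run the full model plus the single-component removal variants."""
    out = {}
    for name, overrides in (arms or ABLATION_ARMS).items():
        out[name] = run_pipeline(table, replace(config, **overrides))
    return out
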