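"""Cluster-informed multi-stage missing-value imputation.

Missing columns are filled one at a time with gradient-boosted tree
regressors: the predictors are the 19 near-complete clustering features, the
m cluster-level mean features, and every column completed in earlier cycles,
so each prediction cycle feeds the next one.  Observed cells are never
altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMRegressor

from .clustering import ClusterModel, cluster_feature_matrix, default_aux_targets
from .errors import DataError
from .schema import ClinicalTable

DEFAULT_GBT_PARAMS = dict(
    n_estimators=200,
    num_leaves=31,
    learning_rate=0.05,
    subsample=0.8,
    subsample_freq=1,
    min_child_samples=20,
    n_jobs=1,
    verbosity=-1,
)


@dataclass
class ImputationPlan:
    """Fill order plus the fixed predictor base.

    ``order`` lists the attributes to fill; an attribute may only depend on
    attributes earlier in the list (plus the predictor base and the auxiliary
    cluster-mean columns).
    """

    order: tuple[str, ...]
    predictor_base: tuple[str, ...]
    aux_targets: tuple[str, ...]
    model_params: dict = field(default_factory=lambda: dict(DEFAULT_GBT_PARAMS))
    seed: int = 0


def plan_imputation(
    table: ClinicalTable,
    cluster_model: ClusterModel,
    order_strategy: str = "schema",
    model_params: dict | None = None,
    seed: int = 0,
) -> ImputationPlan:
    """Default fill order: schema order over the panel groups B, C, D, E
    (starting at B1), skipping attributes with no missing cells.

    ``order_strategy="missing_asc"`` orders by ascending missing count
    instead (ties broken by schema order).
    """
    schema = table.schema
    aux = default_aux_targets(schema)
    fillable = [a for a in aux if (~table.observed[:, schema.index_of(a)]).any()]
    if order_strategy == "missing_asc":
        fillable.sort(key=lambda a: int((~table.observed[:, schema.index_of(a)]).sum()))
    elif order_strategy != "schema":
        raise ValueError(f"unknown order strategy {order_strategy!r}")
    params = dict(DEFAULT_GBT_PARAMS)
    if model_params:
        params.update(model_params)
    return ImputationPlan(
        order=tuple(fillable),
        predictor_base=cluster_model.clustering_features,
        aux_targets=aux,
        model_params=params,
        seed=seed,
    )


def impute_stepwise(
    table: ClinicalTable,
    plan: ImputationPlan,
    cluster_model: ClusterModel,
) -> ClinicalTable:
    """Fill the planned attributes in order with gradient-boosted regressors.

    For each attribute: fit on the patients observing it, predict for those
    missing it, write predictions back (marked in ``imputed``) and make the
    completed column available to later cycles.  Falls back to the cluster
    mean, with a warning, if an attribute has no observed training rows.
    """
    schema = table.schema
    out = table.copy()
    aux, aux_ids = cluster_feature_matrix(cluster_model, table, plan.aux_targets)

    base_idx = [schema.index_of(a) for a in plan.predictor_base]
    base = table.values[:, base_idx].copy()
    for k, j in enumerate(base_idx):  # clustering-feature gaps: median fill
        col = base[:, k]
        gaps = np.isnan(col)
        if gaps.any():
            col[gaps] = np.nanmedian(col)
            # the fill also lands in the output so no predictor cell stays open
            out.values[gaps, j] = col[gaps]
            out.observed[gaps, j] = True
            out.imputed[gaps, j] = True
    predictors = np.concatenate([base, aux], axis=1)

    rng = np.random.default_rng(plan.seed)
    for a in plan.order:
        j = schema.index_of(a)
        obs = out.observed[:, j]
        miss = ~obs
        if not miss.any():
            continue
        if not obs.any():
            warnings.warn(
                f"attribute {a} has no observed training rows; cluster-mean fill",
                stacklevel=2,
            )
            fill = aux[miss, aux_ids.index(a)]
        else:
            model = LGBMRegressor(
                **plan.model_params,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sklearn feature-name chatter
                model.fit(predictors[obs], out.values[obs, j])
                fill = model.predict(predictors[miss])
        out.values[miss, j] = fill
        out.observed[miss, j] = True
        out.imputed[miss, j] = True
        predictors = np.concatenate([predictors, out.values[:, [j]]], axis=1)
    return out


def mean_fill_baseline(table: ClinicalTable) -> ClinicalTable:
    """Column-mean (numeric) / column-mode (categorical) fill — the simple
    baseline the stepwise strategy is measured against."""
    out = table.copy()
    for j, a in enumerate(table.schema.attributes):
        obs = table.observed[:, j]
        miss = ~obs
        if not miss.any():
            continue
        if not obs.any():
            raise DataError(f"column {a.attribute_id} is entirely missing")
        col = table.values[obs, j]
        if a.kind == "categorical":
            vals, counts = np.unique(col, return_counts=True)
            fill = vals[counts.argmax()]
        else:
            fill = col.mean()
        out.values[miss, j] = fill
        out.observed[miss, j] = True
        out.imputed[miss, j] = True
    return out
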