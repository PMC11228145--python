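"""Synthetic clinical tables with the structure the framework assumes.

The generator emulates four properties of routine examination data: latent
patient clusters (people with similar physiology have correlated panels), the
seven-group attribute layout, group-structured missingness (a patient skips a
whole test panel, e.g. the lipid profile), and a continuous blood-glucose-like
target driven by a sparse subset of feature groups (liver function and lipid
profile by default).  It makes no attempt to match the marginal distributions
of real laboratory analytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .schema import ClinicalTable, FeatureSchema, canonical_schema

#: groups whose missingness is panel-wise (whole group skipped per patient)
PANEL_MISSING_GROUPS = ("B", "C", "D", "E")
#: near-complete groups: cell-level dropout only (demographics stay complete)
CELL_MISSING_GROUPS = ("F", "G")


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 1000
    n_clusters: int = 3
    cluster_sep: float = 3.0
    signal_groups: tuple[str, ...] = ("B", "D")
    coef_scale: float = 1.0
    noise_sd: float = 1.0
    group_missing_prob: float = 0.3
    cell_missing_prob: float = 0.02
    #: positive per-column baseline levels, as in real laboratory analytes;
    #: they anchor the mean-proportional perturbation half-width eps_f
    column_base_range: tuple[float, float] = (5.0, 50.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_clusters < 1:
            raise ParameterError("n_patients and n_clusters must be >= 1")
        for p in (self.group_missing_prob, self.cell_missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must lie in [0, 1]")
        if self.noise_sd < 0 or self.cluster_sep < 0:
            raise ParameterError("noise_sd and cluster_sep must be >= 0")


def simulate_table(
    config: SimulationConfig, schema: FeatureSchema | None = None
) -> tuple[ClinicalTable, dict]:
    """Draw a clinical-like table plus its ground truth.

    Per patient: a latent cluster c is drawn uniformly; every indicator
    column (groups B-G) is its cluster mean plus unit-variance Gaussian
    noise; age is a truncated normal and gender Bernoulli(0.5), both
    cluster-independent.  The target is

        y = intercept + sum_j coef_j * (x_j - baseline_j) + Normal(0, noise_sd)

    with nonzero coef_j only on ``signal_groups``; baselines are the
    positive per-column reference levels, so y stays near the
    fasting-glucose-like intercept.  Masking: each panel
    group (B-E) is dropped wholesale per patient with ``group_missing_prob``,
    then indicator cells drop out with ``cell_missing_prob``; demographics
    stay complete.

    Returns ``(table, ground_truth)`` where ground truth holds the cluster
    labels, the coefficient vector, the intercept and the pre-masking matrix.
    """
    config.validate()
    schema = schema or canonical_schema()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, schema.n_attributes

    indicator_ids = [a.attribute_id for a in schema.attributes if a.group_id != "A"]
    ind_idx = np.array([schema.index_of(a) for a in indicator_ids])

    lo, hi = config.column_base_range
    if lo > hi or lo < 0:
        raise ParameterError("column_base_range must satisfy 0 <= lo <= hi")
    bases = rng.uniform(lo, hi, size=len(ind_idx))
    centers = bases + rng.normal(
        0.0, config.cluster_sep, size=(config.n_clusters, len(ind_idx))
    )
    labels = rng.integers(0, config.n_clusters, size=n)

    values = np.empty((n, p))
    age_idx = schema.index_of("A1")
    gender_idx = schema.index_of("A2")
    age = rng.normal(45.0, 15.0, size=n)
    values[:, age_idx] = np.clip(age, 18.0, 90.0)
    values[:, gender_idx] = rng.integers(0, 2, size=n)
    values[:, ind_idx] = centers[labels] + rng.normal(size=(n, len(ind_idx)))

    coefs = np.zeros(p)
    for g in config.signal_groups:
        for a in schema.group_members(g):
            coefs[schema.index_of(a)] = rng.normal(0.0, config.coef_scale)
    # the target responds to deviations from the column reference levels, so
    # its scale stays near the fasting-glucose-like intercept
    baselines = np.empty(p)
    baselines[age_idx] = 45.0
    baselines[gender_idx] = 0.5
    baselines[ind_idx] = bases
    intercept = 5.5
    target = (intercept + (values - baselines) @ coefs
              + rng.normal(0.0, config.noise_sd, size=n))

    complete = values.copy()
    observed = np.ones((n, p), dtype=bool)
    for g in PANEL_MISSING_GROUPS:
        gi = np.array([schema.index_of(a) for a in schema.group_members(g)])
        drop = rng.random(n) < config.group_missing_prob
        observed[np.ix_(drop, gi)] = False
    if config.cell_missing_prob > 0:
        cell = rng.random((n, len(ind_idx))) < config.cell_missing_prob
        obs_ind = observed[:, ind_idx]
        observed[:, ind_idx] = obs_ind & ~cell

    table = ClinicalTable(schema=schema, values=values, observed=observed, target=target)
    truth = {
        "labels": labels,
        "coefficients": coefs,
        "intercept": intercept,
        "baselines": baselines,
        "complete_values": complete,
        "config": config,
    }
    return table, truth


_FIXTURE_CONFIG = SimulationConfig(
    n_patients=16,
    n_clusters=2,
    cluster_sep=4.0,
    group_missing_prob=0.35,
    cell_missing_prob=0.02,
    noise_sd=0.5,
    seed=7,
)


def simulate_worked_fixture() -> ClinicalTable:
    """Small deterministic table (16 patients) used across module tests.

    Patient 0 is forced to miss the entire hepatitis-B panel (group E) so the
    panel-missing code paths are always exercised.
    """
    table, _ = simulate_table(_FIXTURE_CONFIG)
    schema = table.schema
    e_idx = [schema.index_of(a) for a in schema.group_members("E")]
    table.observed[0, e_idx] = False
    table.values[0, e_idx] = np.nan
    return table
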