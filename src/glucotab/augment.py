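"""Dual-layer data augmentation.

Sample augmentation adds, to copies of each patient, bounded random
perturbations Δ_f drawn uniformly on (−ε_f, ε_f) for n randomly chosen
indicator features, with ε_f one-twentieth of the feature's training-column
mean by default; two copies per patient.  Feature augmentation clusters
patients on all numeric predictor columns and appends, for selected clinical
groups, each member attribute's cluster-mean as an extra ``<id>_grp`` column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import NOISE_LABEL, cluster_patients
from .errors import ParameterError
from .schema import Attribute, ClinicalTable, require_complete

#: clinical indicator groups eligible for perturbation (age/gender excluded)
INDICATOR_GROUPS = ("B", "C", "D", "E", "F", "G")


def eligible_perturb_features(schema) -> tuple[str, ...]:
    """Numeric indicator attributes, excluding demographics and any appended
    ``_grp`` cluster-mean columns (deterministic functions of other columns)."""
    out = []
    for a in schema.attributes:
        if a.kind == "numeric" and a.group_id in INDICATOR_GROUPS:
            out.append(a.attribute_id)
    return tuple(out)


@dataclass
class PerturbSpec:
    n_perturb: int = 10
    epsilon_ratio: float = 1.0 / 20.0
    copies_per_patient: int = 2
    eligible: tuple[str, ...] | None = None
    column_means: dict[str, float] | None = None  # training means for eps_f
    seed: int = 0

    def validate(self, schema) -> tuple[str, ...]:
        eligible = tuple(self.eligible or eligible_perturb_features(schema))
        if self.epsilon_ratio < 0:
            raise ParameterError("epsilon_ratio must be nonnegative")
        if not 1 <= self.n_perturb <= len(eligible):
            raise ParameterError(
                f"n_perturb must be in [1, {len(eligible)}], got {self.n_perturb}"
            )
        if self.copies_per_patient < 0:
            raise ParameterError("copies_per_patient must be >= 0")
        return eligible


@dataclass
class GroupAugmentSpec:
    selected_groups: tuple[str, ...] = ("B", "D")
    eps: float | None = None
    min_samples: int = 10

    def validate(self, schema) -> None:
        for g in self.selected_groups:
            if g not in schema.group_ids:
                raise ParameterError(f"unknown group {g!r}")


def perturbation_halfwidths(
    table: ClinicalTable, spec: PerturbSpec, eligible: tuple[str, ...]
) -> np.ndarray:
    """ε_f per eligible feature: epsilon_ratio × |training-column mean|.

    The absolute value guards synthetic columns with negative means; on
    clinical data (positive analytes) it is the plain column mean.
    """
    eps = np.empty(len(eligible))
    for k, a in enumerate(eligible):
        if spec.column_means is not None:
            mean = spec.column_means[a]
        else:
            mean = float(np.nanmean(table.column(a)))
        eps[k] = spec.epsilon_ratio * abs(mean)
    return eps


def _perturb_rows(
    values: np.ndarray,
    eligible_idx: np.ndarray,
    eps: np.ndarray,
    n_perturb: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Shift ``n_perturb`` distinct eligible features of every row in place
    (on a copy); returns the copy and the perturbed (row, column) cells."""
    out = values.copy()
    cells = []
    for i in range(len(out)):
        chosen = rng.choice(len(eligible_idx), size=n_perturb, replace=False)
        for k in chosen:
            e = eps[k]
            if e == 0.0:
                continue
            delta = rng.uniform(-e, e)
            while delta == 0.0:  # keep the interval open and the cell changed
                delta = rng.uniform(-e, e)
            out[i, eligible_idx[k]] += delta
            cells.append((i, int(eligible_idx[k])))
    return out, cells


def augment_samples(
    table: ClinicalTable,
    spec: PerturbSpec,
    return_manifest: bool = False,
):
    """Originals plus ``copies_per_patient`` perturbed copies of each patient.

    Every copy differs from its source in exactly ``n_perturb`` cells (fewer
    only where ε_f is zero), each by strictly less than its ε_f; targets and
    all other cells are bit-identical.  Requires a complete table.
    """
    require_complete(table, "augment_samples")
    eligible = spec.validate(table.schema)
    eps = perturbation_halfwidths(table, spec, eligible)
    eligible_idx = np.array([table.schema.index_of(a) for a in eligible])
    rng = np.random.default_rng(spec.seed)

    blocks = [table.values]
    targets = [table.target] if table.target is not None else None
    manifest: list[dict] = []
    for c in range(spec.copies_per_patient):
        pert, cells = _perturb_rows(table.values, eligible_idx, eps, spec.n_perturb, rng)
        blocks.append(pert)
        if targets is not None:
            targets.append(table.target)
        manifest.append({"copy": c, "cells": cells})

    values = np.concatenate(blocks, axis=0)
    out = ClinicalTable(
        schema=table.schema,
        values=values,
        observed=np.ones_like(values, dtype=bool),
        target=None if targets is None else np.concatenate(targets),
    )
    if return_manifest:
        return out, manifest
    return out


def grp_attribute(source: Attribute) -> Attribute:
    return Attribute(
        attribute_id=f"{source.attribute_id}_grp",
        name=f"{source.name} (cluster mean)",
        group_id=f"{source.group_id}_grp",
        kind="numeric",
    )


def augment_group_features(
    table: ClinicalTable,
    spec: GroupAugmentSpec,
) -> ClinicalTable:
    """Append group-level cluster-mean columns for the selected groups.

    Patients are clustered with DBSCAN on ALL numeric predictor columns
    (z-scored); for every attribute of every selected group one ``<id>_grp``
    column holds that attribute's mean over the patient's cluster (noise
    points fall back to the global mean).  The schema gains one new group tag
    per source group (``B_grp``, ``D_grp``, ...).
    """
    require_complete(table, "augment_group_features")
    spec.validate(table.schema)
    if not spec.selected_groups:
        warnings.warn("no groups selected; table returned unchanged", stacklevel=2)
        return table

    schema = table.schema
    numeric = tuple(a.attribute_id for a in schema.attributes if a.kind == "numeric")
    model = cluster_patients(
        table, clustering_features=numeric, eps=spec.eps,
        min_samples=spec.min_samples, standardize=True,
    )

    new_attrs: list[Attribute] = []
    cols: list[np.ndarray] = []
    for g in spec.selected_groups:
        for aid in schema.group_members(g):
            src = schema.attribute(aid)
            j = schema.index_of(aid)
            col = np.empty(table.n_patients)
            for i, lab in enumerate(model.labels):
                if lab == NOISE_LABEL:
                    col[i] = model.global_means[j]
                else:
                    col[i] = model.cluster_means[int(lab)][j]
            new_attrs.append(grp_attribute(src))
            cols.append(col)

    values = np.concatenate([table.values] + [c[:, None] for c in cols], axis=1)
    return ClinicalTable(
        schema=schema.with_appended(new_attrs),
        values=values,
        observed=np.ones_like(values, dtype=bool),
        target=None if table.target is None else table.target.copy(),
        ids=None if table.ids is None else table.ids.copy(),
    )
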