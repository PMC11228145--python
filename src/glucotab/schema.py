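"""Clinical data model: attribute schema, in-memory table, CSV round-trip.

The canonical schema mirrors a routine physical-examination panel: two
demographic attributes (age, gender) plus 37 numeric medical-test indicators
organised in six clinical groups —

    B  liver function tests            (8 indicators)
    C  kidney function tests           (3)
    D  lipid profile                   (4)
    E  hepatitis B virus markers       (5)
    F  complete blood count            (12)
    G  white-blood-cell differential   (5)

— and a continuous blood-glucose target.  Missingness is carried as an
explicit boolean ``observed`` mask; unobserved cells hold NaN and are never
read by downstream numerics.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ParseError, SchemaError

#: accepted spellings of a missing cell on disk
DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan")

#: gender coding: male -> 1, female -> 0
GENDER_CODES: Mapping[str, int] = {
    "male": 1, "m": 1, "1": 1,
    "female": 0, "f": 0, "0": 0,
}

CANONICAL_GROUP_SIZES = {"A": 2, "B": 8, "C": 3, "D": 4, "E": 5, "F": 12, "G": 5}


@dataclass(frozen=True)
class Attribute:
    attribute_id: str
    name: str
    group_id: str
    kind: str  # "numeric" | "categorical"

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise SchemaError(f"unknown attribute kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered attribute catalogue plus the name of the regression target."""

    attributes: tuple[Attribute, ...]
    target_name: str = "blood_glucose"

    def __post_init__(self) -> None:
        ids = [a.attribute_id for a in self.attributes]
        if len(set(ids)) != len(ids):
            raise SchemaError("attribute ids are not unique")
        if self.target_name in ids:
            raise SchemaError("target column must not be a predictor attribute")

    # -- lookup helpers -------------------------------------------------
    @property
    def attribute_ids(self) -> tuple[str, ...]:
        return tuple(a.attribute_id for a in self.attributes)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @functools.cached_property
    def _index(self) -> dict[str, int]:
        return {a.attribute_id: i for i, a in enumerate(self.attributes)}

    def index_of(self, attribute_id: str) -> int:
        try:
            return self._index[attribute_id]
        except KeyError:
            raise SchemaError(f"unknown attribute id {attribute_id!r}") from None

    def attribute(self, attribute_id: str) -> Attribute:
        return self.attributes[self.index_of(attribute_id)]

    @property
    def group_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a in self.attributes:
            if a.group_id not in seen:
                seen.append(a.group_id)
        return tuple(seen)

    def group_members(self, group_id: str) -> tuple[str, ...]:
        return tuple(a.attribute_id for a in self.attributes if a.group_id == group_id)

    def numeric_ids(self) -> tuple[str, ...]:
        return tuple(a.attribute_id for a in self.attributes if a.kind == "numeric")

    def categorical_ids(self) -> tuple[str, ...]:
        return tuple(a.attribute_id for a in self.attributes if a.kind == "categorical")

    def with_appended(self, extra: Sequence[Attribute]) -> "FeatureSchema":
        return FeatureSchema(self.attributes + tuple(extra), self.target_name)


@functools.lru_cache(maxsize=1)
def canonical_schema() -> FeatureSchema:
    """The packaged seven-group schema (39 predictor columns)."""
    text = resources.files("glucotab.data").joinpath("canonical_schema.yaml").read_text()
    raw = yaml.safe_load(text)
    attrs = tuple(
        Attribute(a["id"], a["name"], a["group"], a["kind"]) for a in raw["attributes"]
    )
    schema = FeatureSchema(attrs, raw["target_name"])
    sizes = {g: len(schema.group_members(g)) for g in schema.group_ids}
    if sizes != CANONICAL_GROUP_SIZES:  # defensive: packaged file edited
        raise SchemaError(f"canonical group sizes corrupted: {sizes}")
    return schema


@dataclass
class ClinicalTable:
    """Patient x attribute matrix with an explicit missingness mask.

    ``values`` is float64 with NaN at unobserved cells (categorical columns
    integer-coded); ``observed`` marks presence, ``imputed`` marks cells that
    were filled by an imputation stage (a subset of observed).
    """

    schema: FeatureSchema
    values: np.ndarray
    observed: np.ndarray
    target: np.ndarray | None = None
    ids: np.ndarray | None = None
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise SchemaError("values and observed shapes differ")
        if self.values.ndim != 2 or self.values.shape[1] != self.schema.n_attributes:
            raise SchemaError(
                f"expected {self.schema.n_attributes} predictor columns, "
                f"got {self.values.shape[1] if self.values.ndim == 2 else '?'}"
            )
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if len(self.target) != len(self.values):
                raise SchemaError("target length differs from row count")
        if self.imputed is None:
            self.imputed = np.zeros_like(self.observed)
        # unobserved cells hold the NaN sentinel
        self.values = self.values.copy()
        self.values[~self.observed] = np.nan

    # -- basic accessors ------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    def column_index(self, attribute_id: str) -> int:
        return self.schema.index_of(attribute_id)

    def column(self, attribute_id: str) -> np.ndarray:
        return self.values[:, self.column_index(attribute_id)]

    @property
    def is_complete(self) -> bool:
        return bool(self.observed.all())

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(
            schema=self.schema,
            values=self.values.copy(),
            observed=self.observed.copy(),
            target=None if self.target is None else self.target.copy(),
            ids=None if self.ids is None else self.ids.copy(),
            imputed=None if self.imputed is None else self.imputed.copy(),
        )

    def take(self, idx: np.ndarray) -> "ClinicalTable":
        """Row subset (used for train/valid/test splitting)."""
        idx = np.asarray(idx)
        return ClinicalTable(
            schema=self.schema,
            values=self.values[idx],
            observed=self.observed[idx],
            target=None if self.target is None else self.target[idx],
            ids=None if self.ids is None else self.ids[idx],
            imputed=None if self.imputed is None else self.imputed[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {}
        if self.ids is not None:
            cols["id"] = self.ids
        for j, a in enumerate(self.schema.attributes):
            col = self.values[:, j].astype(object)
            col[~self.observed[:, j]] = None
            cols[a.name] = col
        if self.target is not None:
            cols[self.schema.target_name] = self.target
        return pd.DataFrame(cols)


def _parse_gender(raw: pd.Series, colname: str) -> np.ndarray:
    out = np.empty(len(raw), dtype=float)
    for i, v in enumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ParseError(f"missing gender in column {colname!r} at row {i}")
        token = str(v).strip().lower()
        if token.endswith(".0"):
            token = token[:-2]
        if token not in GENDER_CODES:
            raise ParseError(f"unknown gender token {v!r} at row {i}")
        out[i] = GENDER_CODES[token]
    return out


def load_table(
    path,
    schema: FeatureSchema | None = None,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> ClinicalTable:
    """Read a delimited table whose header names the schema attributes.

    Optional ``id``/``date`` columns are stored but flagged non-model; a
    column named like the schema target becomes the regression target.
    Raises :class:`SchemaError` for a missing required column and
    :class:`ParseError` (with the row index) for a non-numeric token in a
    numeric column.
    """
    schema = schema or canonical_schema()
    na = list(na_tokens)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=na)

    missing = [a.name for a in schema.attributes if a.name not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    n = len(df)
    values = np.full((n, schema.n_attributes), np.nan)
    for j, a in enumerate(schema.attributes):
        raw = df[a.name]
        if a.kind == "categorical":
            values[:, j] = _parse_gender(raw, a.name)
            continue
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric token {raw.iloc[row]!r} in column {a.name!r} at row {row}"
            )
        values[:, j] = parsed.to_numpy(dtype=float)
    observed = ~np.isnan(values)

    target = None
    if schema.target_name in df.columns:
        parsed = pd.to_numeric(df[schema.target_name], errors="coerce")
        bad = parsed.isna() & df[schema.target_name].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric target at row {row}")
        target = parsed.to_numpy(dtype=float)

    ids = None
    for cand in ("id", "ID", "Id"):
        if cand in df.columns:
            ids = df[cand].to_numpy()
            break
    return ClinicalTable(schema=schema, values=values, observed=observed,
                         target=target, ids=ids)


def write_table(table: ClinicalTable, path) -> None:
    """Write a table as comma-delimited text; unobserved cells become empty
    fields, so ``load_table(write_table(t))`` reproduces the mask exactly."""
    df = table.to_dataframe()
    # full round-trip precision for floats
    df.to_csv(path, index=False, na_rep="", float_format="%.17g")


def missingness_summary(table: ClinicalTable) -> dict:
    """Per-attribute missing counts plus per-group all-missing patient counts."""
    miss = ~table.observed
    per_attr = {
        a.attribute_id: int(miss[:, j].sum())
        for j, a in enumerate(table.schema.attributes)
    }
    per_group = {}
    for g in table.schema.group_ids:
        idx = [table.schema.index_of(a) for a in table.schema.group_members(g)]
        per_group[g] = int(miss[:, idx].all(axis=1).sum())
    return {
        "per_attribute_missing": per_attr,
        "per_group_all_missing": per_group,
        "total_missing": int(miss.sum()),
    }


def require_complete(table: ClinicalTable, stage: str) -> None:
    if not table.is_complete:
        raise DataError(f"{stage}: table has unobserved cells; impute first")
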