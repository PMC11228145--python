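"""Patient clustering and cluster-level mean features.

Patients are grouped with DBSCAN on a low-missingness feature set — by
default the 19 near-complete attributes (age, gender, the complete blood
count and the white-cell differential) — and each cluster contributes
per-attribute mean features used by the imputation stage.  A second,
all-feature clustering serves the group-level feature augmentation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError, SchemaError
from .schema import ClinicalTable, FeatureSchema

NOISE_LABEL = -1

#: default clustering attributes: demographics + CBC + differential (19)
DEFAULT_CLUSTERING_GROUPS = ("A", "F", "G")
#: default auxiliary targets: the 20 attributes of the panel groups
DEFAULT_AUX_GROUPS = ("B", "C", "D", "E")


def default_clustering_features(schema: FeatureSchema) -> tuple[str, ...]:
    out: list[str] = []
    for g in DEFAULT_CLUSTERING_GROUPS:
        out.extend(schema.group_members(g))
    return tuple(out)


def default_aux_targets(schema: FeatureSchema) -> tuple[str, ...]:
    out: list[str] = []
    for g in DEFAULT_AUX_GROUPS:
        out.extend(schema.group_members(g))
    return tuple(out)


@dataclass
class ClusterModel:
    """DBSCAN labels plus per-cluster / global observed-value means.

    ``cluster_means[c][j]`` is the arithmetic mean of observed values of
    attribute j among members of cluster c, falling back to
    ``global_means[j]`` when no member observes j.  Noise points carry
    :data:`NOISE_LABEL`.
    """

    labels: np.ndarray
    clustering_features: tuple[str, ...]
    cluster_means: dict[int, np.ndarray]
    global_means: np.ndarray
    params: dict
    # standardisation recipe, kept so unseen rows can be assigned later
    feature_medians: np.ndarray = field(default=None, repr=False)
    feature_loc: np.ndarray = field(default=None, repr=False)
    feature_scale: np.ndarray = field(default=None, repr=False)
    centroids: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.cluster_means)

    def assign(self, table: ClinicalTable) -> np.ndarray:
        """Nearest-centroid label assignment for rows not seen at fit time."""
        if not self.centroids:
            return np.full(table.n_patients, NOISE_LABEL)
        X = _clustering_matrix(table, self.clustering_features, self.feature_medians)
        X = (X - self.feature_loc) / self.feature_scale
        ids = list(self.centroids)
        C = np.stack([self.centroids[c] for c in ids])
        d = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        return np.array(ids)[d.argmin(axis=1)]


def _clustering_matrix(
    table: ClinicalTable, features: tuple[str, ...], medians: np.ndarray
) -> np.ndarray:
    idx = [table.schema.index_of(a) for a in features]
    X = table.values[:, idx].copy()
    for k in range(X.shape[1]):
        col = X[:, k]
        col[np.isnan(col)] = medians[k]
    return X


def estimate_eps(X: np.ndarray, min_samples: int, quantile: float = 0.90) -> float:
    """k-distance heuristic: the ``quantile`` of k-NN distances, k = min_samples."""
    k = min(min_samples, len(X) - 1)
    if k < 1:
        return 1.0
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    eps = float(np.quantile(dist[:, -1], quantile))
    return eps if eps > 0 else 1.0


def cluster_patients(
    table: ClinicalTable,
    clustering_features: tuple[str, ...] | None = None,
    eps: float | None = None,
    min_samples: int = 10,
    standardize: bool = True,
) -> ClusterModel:
    """DBSCAN over the (median-filled, optionally z-scored) clustering features.

    Cluster and global means are computed from the ORIGINAL observed cells
    only.  If every point is classified as noise the model degenerates, with
    a warning, to a single global pseudo-cluster.
    """
    schema = table.schema
    feats = tuple(clustering_features or default_clustering_features(schema))
    for a in feats:
        schema.index_of(a)  # raises SchemaError on unknown ids
        j = schema.index_of(a)
        if table.observed[:, j].mean() < 0.5:
            raise SchemaError(f"clustering feature {a} observed for < 50% of patients")
    if min_samples < 1:
        raise ParameterError("min_samples must be >= 1")
    if eps is not None and eps <= 0:
        raise ParameterError("eps must be positive")

    idx = [schema.index_of(a) for a in feats]
    raw = table.values[:, idx]
    medians = np.array([np.nanmedian(raw[:, k]) for k in range(raw.shape[1])])
    medians = np.nan_to_num(medians)
    X = _clustering_matrix(table, feats, medians)
    if standardize:
        loc = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        loc = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - loc) / scale

    if eps is None:
        eps = estimate_eps(Xs, min_samples)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit(Xs).labels_

    if (labels == NOISE_LABEL).all():
        warnings.warn(
            "DBSCAN classified every patient as noise; degenerating to one "
            "global pseudo-cluster",
            stacklevel=2,
        )
        labels = np.zeros(table.n_patients, dtype=int)

    p = schema.n_attributes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice nanmean
        global_means = np.nanmean(table.values, axis=0)
    global_means = np.nan_to_num(global_means)

    cluster_means: dict[int, np.ndarray] = {}
    centroids: dict[int, np.ndarray] = {}
    for c in np.unique(labels):
        if c == NOISE_LABEL:
            continue
        members = labels == c
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(table.values[members], axis=0)
        m[np.isnan(m)] = global_means[np.isnan(m)]
        cluster_means[int(c)] = m
        centroids[int(c)] = Xs[members].mean(axis=0)

    return ClusterModel(
        labels=labels,
        clustering_features=feats,
        cluster_means=cluster_means,
        global_means=global_means,
        params={"eps": float(eps), "min_samples": int(min_samples),
                "standardize": bool(standardize)},
        feature_medians=medians,
        feature_loc=loc,
        feature_scale=scale,
        centroids=centroids,
    )


def cluster_feature_matrix(
    model: ClusterModel,
    table: ClinicalTable,
    target_attributes: tuple[str, ...] | None = None,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Patient x m auxiliary matrix of cluster-level means.

    Row p, column j holds the mean of attribute j within patient p's cluster;
    noise-labelled patients receive the global mean.  The output never
    contains missing values.
    """
    schema = table.schema
    targets = tuple(target_attributes or default_aux_targets(schema))
    idx = [schema.index_of(a) for a in targets]  # SchemaError on unknown id
    if labels is None:
        labels = model.labels
    if len(labels) != table.n_patients:
        labels = model.assign(table)

    out = np.empty((table.n_patients, len(targets)))
    fallback = model.global_means[idx]
    for i, lab in enumerate(labels):
        if lab == NOISE_LABEL or int(lab) not in model.cluster_means:
            out[i] = fallback
        else:
            out[i] = model.cluster_means[int(lab)][idx]
    return out, targets
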