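import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from glucotab import (
    SimulationConfig,
    cluster_feature_matrix,
    cluster_patients,
    simulate_table,
)
from glucotab.clustering import (
    NOISE_LABEL,
    default_aux_targets,
    default_clustering_features,
)
from glucotab.errors import ParameterError, SchemaError


def test_default_clustering_feature_set_has_19_members(schema):
    feats = default_clustering_features(schema)
    assert len(feats) == 19
    assert feats[:2] == ("A1", "A2")
    assert all(f.startswith(("A", "F", "G")) for f in feats)


def test_default_aux_targets_are_the_20_panel_attributes(schema):
    targets = default_aux_targets(schema)
    assert len(targets) == 20
    assert targets[0] == "B1" and targets[-1] == "E5"


def test_separated_compact_clouds_give_two_clusters_no_noise(schema):
    """Two tight point clouds far apart relative to eps: every point is a
    core point of its cloud and nothing is noise."""
    from glucotab import ClinicalTable
    rng = np.random.default_rng(9)
    n = 200
    values = rng.uniform(-0.5, 0.5, size=(n, schema.n_attributes))
    values[:, schema.index_of("A2")] = rng.integers(0, 2, n)
    truth = np.repeat([0, 1], n // 2)
    values[truth == 1] += 25.0
    table = ClinicalTable(schema, values, np.ones_like(values, dtype=bool))
    model = cluster_patients(table, standardize=False, min_samples=5)
    assert set(model.labels) == {0, 1}
    assert (model.labels != NOISE_LABEL).all()
    assert adjusted_rand_score(truth, model.labels) == 1.0


def test_label_recovery_on_three_clusters(clustered_sim):
    table, truth = clustered_sim
    model = cluster_patients(table)
    keep = model.labels != NOISE_LABEL
    agree = adjusted_rand_score(truth["labels"][keep], model.labels[keep])
    assert agree >= 0.9


def test_parameter_validation(fixture_table):
    with pytest.raises(ParameterError):
        cluster_patients(fixture_table, eps=0.0)
    with pytest.raises(ParameterError):
        cluster_patients(fixture_table, min_samples=0)
    with pytest.raises(SchemaError):
        cluster_patients(fixture_table, clustering_features=("Z9",))


def test_all_noise_degenerates_to_pseudo_cluster(fixture_table):
    with pytest.warns(UserWarning, match="noise"):
        model = cluster_patients(fixture_table, eps=1e-9, min_samples=10)
    assert set(model.labels) == {0}


class TestClusterFeatureMatrix:
    def test_default_matrix_has_20_columns_no_missing(self, clustered_sim):
        table, _ = clustered_sim
        model = cluster_patients(table)
        aux, ids = cluster_feature_matrix(model, table)
        assert aux.shape == (table.n_patients, 20)
        assert not np.isnan(aux).any()
        assert ids == default_aux_targets(table.schema)

    def test_single_cluster_rows_equal_global_observed_means(self, clustered_sim):
        table, _ = clustered_sim
        model = cluster_patients(table, eps=1e6)  # everything in one cluster
        assert set(model.labels) == {0}
        aux, ids = cluster_feature_matrix(model, table)
        for k, a in enumerate(ids):
            expected = np.nanmean(table.column(a))
            np.testing.assert_allclose(aux[:, k], expected)

    def test_cluster_missing_attribute_falls_back_to_global_mean(self, clustered_sim):
        table, _ = clustered_sim
        table = table.copy()
        model = cluster_patients(table)
        c0 = model.labels == 0
        j = table.schema.index_of("C1")
        table.observed[c0, j] = False
        table.values[c0, j] = np.nan
        refit = cluster_patients(table)
        aux, ids = cluster_feature_matrix(refit, table)
        # patients in a cluster with no observed C1 carry the global mean
        global_c1 = np.nanmean(table.column("C1"))
        k = ids.index("C1")
        members = refit.labels == refit.labels[np.flatnonzero(c0)[0]]
        if not table.observed[members, j].any():
            np.testing.assert_allclose(aux[members, k], global_c1)

    def test_unknown_target_attribute_rejected(self, clustered_sim):
        table, _ = clustered_sim
        model = cluster_patients(table)
        with pytest.raises(SchemaError):
            cluster_feature_matrix(model, table, target_attributes=("Q7",))


def test_cluster_means_are_observed_cell_means(clustered_sim):
    table, _ = clustered_sim
    model = cluster_patients(table)
    c = model.cluster_ids[0]
    members = model.labels == c
    j = table.schema.index_of("B1")
    obs = table.observed[:, j] & members
    if obs.any():
        np.testing.assert_allclose(
            model.cluster_means[c][j], table.values[obs, j].mean()
        )


def test_row_permutation_equivariance(clustered_sim):
    table, _ = clustered_sim
    model = cluster_patients(table)
    perm = np.random.default_rng(0).permutation(table.n_patients)
    permuted = cluster_patients(table.take(perm))
    assert adjusted_rand_score(model.labels[perm], permuted.labels) == 1.0
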