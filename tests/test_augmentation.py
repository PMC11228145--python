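import numpy as np
import pytest

from glucotab import (
    GroupAugmentSpec,
    PerturbSpec,
    augment_group_features,
    augment_samples,
)
from glucotab.augment import eligible_perturb_features, perturbation_halfwidths
from glucotab.errors import DataError, ParameterError
from conftest import make_complete_table


def test_eligible_set_excludes_demographics(schema):
    eligible = eligible_perturb_features(schema)
    assert "A1" not in eligible and "A2" not in eligible
    assert len(eligible) == 37


class TestSampleAugmentation:
    def test_row_count_with_two_copies(self, schema):
        table = make_complete_table(schema, n=5)
        out = augment_samples(table, PerturbSpec(seed=0))
        assert out.n_patients == 15
        # originals appear unmodified, in order, at the head
        assert np.array_equal(out.values[:5], table.values)
        assert np.array_equal(out.target[:5], table.target)

    def test_zero_copies_is_identity(self, schema):
        table = make_complete_table(schema, n=6)
        out = augment_samples(table, PerturbSpec(copies_per_patient=0))
        assert np.array_equal(out.values, table.values)

    def test_perturbation_bound_is_mean_over_twenty(self, schema):
        table = make_complete_table(schema, n=30, seed=1)
        j = table.schema.index_of("B1")
        table.values[:, j] = 40.0  # training mean 40 -> eps = 2
        spec = PerturbSpec(seed=3)
        out = augment_samples(table, spec)
        copies = out.values[30:]
        deltas = copies[:, j] - np.tile(table.values[:, j], 2)
        changed = deltas != 0
        assert np.abs(deltas[changed]).max() < 2.0

    def test_each_copy_differs_in_exactly_n_perturb_cells(self, schema):
        table = make_complete_table(schema, n=20, seed=2)
        spec = PerturbSpec(n_perturb=10, seed=5)
        out = augment_samples(table, spec)
        eligible = eligible_perturb_features(schema)
        eps = perturbation_halfwidths(table, spec, eligible)
        eps_by_col = dict(zip((schema.index_of(a) for a in eligible), eps))
        for c in range(2):
            block = out.values[(c + 1) * 20:(c + 2) * 20]
            diff = block != table.values
            assert (diff.sum(axis=1) == 10).all()
            rows, cols = np.nonzero(diff)
            for r, j in zip(rows, cols):
                delta = abs(block[r, j] - table.values[r, j])
                assert delta < eps_by_col[j]
        assert np.array_equal(out.target, np.tile(table.target, 3))

    def test_deterministic_given_seed(self, schema):
        table = make_complete_table(schema, n=10)
        a = augment_samples(table, PerturbSpec(seed=9)).values
        b = augment_samples(table, PerturbSpec(seed=9)).values
        assert np.array_equal(a, b)

    def test_incomplete_table_rejected(self, fixture_table):
        with pytest.raises(DataError):
            augment_samples(fixture_table, PerturbSpec())

    def test_n_perturb_beyond_eligible_rejected(self, schema):
        table = make_complete_table(schema, n=4)
        with pytest.raises(ParameterError):
            augment_samples(table, PerturbSpec(n_perturb=38))


class TestGroupFeatureAugmentation:
    def test_default_groups_append_12_columns(self, schema):
        table = make_complete_table(schema, n=60, seed=4)
        out = augment_group_features(table, GroupAugmentSpec())
        assert out.values.shape[1] == 39 + 12
        appended = out.schema.attribute_ids[39:]
        assert appended == tuple(
            f"{a}_grp" for g in ("B", "D") for a in schema.group_members(g)
        )
        assert out.schema.group_members("B_grp") == tuple(
            f"B{i}_grp" for i in range(1, 9)
        )

    def test_all_indicator_groups_append_37_columns(self, schema):
        table = make_complete_table(schema, n=60, seed=4)
        spec = GroupAugmentSpec(selected_groups=("B", "C", "D", "E", "F", "G"))
        out = augment_group_features(table, spec)
        assert out.values.shape[1] == 39 + 37

    def test_single_cluster_appends_constant_columns(self, schema):
        table = make_complete_table(schema, n=40, seed=6)
        out = augment_group_features(table, GroupAugmentSpec(eps=1e6))
        appended = out.values[:, 39:]
        assert np.allclose(appended, appended[0])
        np.testing.assert_allclose(
            appended[0, 0], table.column("B1").mean()
        )

    def test_same_cluster_members_share_appended_values(self, clustered_sim):
        from glucotab import cluster_patients, mean_fill_baseline
        table, _ = clustered_sim
        complete = mean_fill_baseline(table)
        out = augment_group_features(complete, GroupAugmentSpec())
        numeric = tuple(a.attribute_id for a in complete.schema.attributes
                        if a.kind == "numeric")
        model = cluster_patients(complete, clustering_features=numeric)
        for c in model.cluster_ids[:2]:
            members = np.flatnonzero(model.labels == c)
            if len(members) > 1:
                block = out.values[members][:, 39:]
                assert np.allclose(block, block[0])

    def test_empty_selection_warns_and_returns_input(self, schema):
        table = make_complete_table(schema, n=10)
        with pytest.warns(UserWarning):
            out = augment_group_features(table, GroupAugmentSpec(selected_groups=()))
        assert out is table
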