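import numpy as np
import pytest

from glucotab import (
    ClinicalTable,
    GroupMaskedTabNet,
    MaskUnitPartition,
    TabNetConfig,
    sparsemax,
)
from glucotab.errors import DataError, ParameterError, SchemaError
from reference_impl import brute_force_simplex_projection, reference_forward_per_feature


def tiny_config(**kw):
    base = dict(n_steps=3, n_d=4, n_a=4, batch=64, virtual_batch=32,
                max_epochs=8, patience=8, seed=0)
    base.update(kw)
    return TabNetConfig(**base)


def random_input(schema, n=64, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, schema.n_attributes))
    X[:, schema.index_of("A2")] = rng.integers(0, 2, n)
    return X


def planted_tables(schema, n=1200, seed=0, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, schema.n_attributes))
    X[:, schema.index_of("A2")] = rng.integers(0, 2, n)
    y = (3 * X[:, schema.index_of("B1")]
         - 2 * X[:, schema.index_of("D1")]
         + rng.normal(0, noise, n))
    obs = np.ones_like(X, dtype=bool)
    cut1, cut2 = int(0.8 * n), int(0.9 * n)
    mk = lambda sl: ClinicalTable(schema, X[sl], obs[sl], y[sl])
    return mk(slice(0, cut1)), mk(slice(cut1, cut2)), mk(slice(cut2, n))


class TestPartition:
    def test_default_partition_units(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        ids = part.unit_ids
        assert "B" in ids and "D" in ids
        # 39 columns: B(8) and D(4) collapse to one unit each
        assert part.n_units == 39 - 8 - 4 + 2
        G = part.membership()
        assert G.sum() == 39
        assert (G.sum(axis=0) == 1).all()

    def test_partition_validation(self):
        with pytest.raises(SchemaError):
            MaskUnitPartition((("u", ()),), 1)
        with pytest.raises(SchemaError):
            MaskUnitPartition((("u", (0,)), ("v", (0,))), 1)
        with pytest.raises(SchemaError):
            MaskUnitPartition((("u", (0,)),), 2)

    def test_config_validation(self):
        with pytest.raises(ParameterError):
            TabNetConfig(gamma=0.5).validate()
        with pytest.raises(ParameterError):
            TabNetConfig(n_steps=0).validate()


class TestSparsemax:
    def test_symmetry_and_dominance(self):
        np.testing.assert_allclose(sparsemax(np.zeros(5)), np.full(5, 0.2))
        np.testing.assert_allclose(sparsemax(np.array([10.0, 0.0, 0.0])),
                                   [1.0, 0.0, 0.0])

    def test_matches_brute_force_projection(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            z = rng.normal(scale=2.0, size=rng.integers(2, 6))
            np.testing.assert_allclose(
                sparsemax(z), brute_force_simplex_projection(z), atol=1e-8
            )

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            sparsemax(np.array([np.inf, 0.0]))


class TestForward:
    def test_group_mask_equality_is_exact(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config())
        _, trace, _ = model.forward(random_input(schema), training=False)
        for M in trace.feature_masks:
            for uid, members in part.units:
                cols = M[:, list(members)]
                assert (cols == cols[:, [0]]).all()

    def test_attention_rows_sum_to_one(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config(seed=3))
        _, trace, _ = model.forward(random_input(schema, seed=3), training=False)
        for q in trace.unit_attention:
            assert (q >= 0).all()
            np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-5)

    def test_prior_telescoping_at_gamma_one(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config(gamma=1.0, n_steps=4))
        _, trace, _ = model.forward(random_input(schema, seed=5), training=False)
        total = sum(trace.unit_attention)
        assert (total <= 1.0 + 1e-9).all()
        # a fully attended unit is never re-selected
        for i, q in enumerate(trace.unit_attention[:-1]):
            exhausted = q >= 1.0 - 1e-12
            for later in trace.unit_attention[i + 1:]:
                assert (later[exhausted] <= 1e-12).all()

    def test_aggregate_importance_rows_sum_to_one(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config())
        _, trace, _ = model.forward(random_input(schema), training=False)
        agg = trace.aggregate_importance
        assert (agg >= 0).all()
        np.testing.assert_allclose(agg.sum(axis=1), 1.0, atol=1e-5)

    def test_single_step_aggregate_equals_normalized_mask(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config(n_steps=1))
        _, trace, _ = model.forward(random_input(schema, seed=2), training=False)
        M = trace.feature_masks[0]
        rowsum = M.sum(axis=1, keepdims=True)
        keep = (rowsum.ravel() > 0) & (trace.step_strength[0] > 0)
        np.testing.assert_allclose(
            trace.aggregate_importance[keep], (M / rowsum)[keep], atol=1e-10
        )

    def test_singleton_partition_matches_reference_implementation(self, schema):
        part = MaskUnitPartition.singletons(schema.n_attributes, schema.attribute_ids)
        model = GroupMaskedTabNet(schema, part, tiny_config(seed=11))
        X = random_input(schema, n=32, seed=11)
        pred, trace, _ = model.forward(X, training=False)
        ref_pred, ref_masks = reference_forward_per_feature(model, X)
        np.testing.assert_allclose(pred.data.ravel(), ref_pred, atol=1e-8)
        for M, R in zip(trace.feature_masks, ref_masks):
            np.testing.assert_allclose(M, R, atol=1e-8)

    def test_missing_cells_rejected(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config())
        X = random_input(schema)
        X[0, 5] = np.nan
        with pytest.raises(DataError):
            model.forward(X)

    def test_eval_forward_deterministic(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config())
        X = random_input(schema)
        p1, _, _ = model.forward(X, training=False)
        p2, _, _ = model.forward(X, training=False)
        assert np.array_equal(p1.data, p2.data)

    def test_shared_blocks_are_shared_storage(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config())
        # the shared GLU parameters appear exactly once in the parameter list
        ids = [id(p) for p in model.parameters()]
        assert len(ids) == len(set(ids))
        assert len(model.shared) == model.config.n_shared


class TestFit:
    def test_learns_planted_linear_signal(self, schema):
        train, valid, test = planted_tables(schema, n=1200, seed=4)
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config(
            n_d=8, n_a=8, max_epochs=25, patience=25, seed=4))
        log = model.fit(train, valid)
        best_val = min(entry["val_mse"] for entry in log)
        assert best_val < train.target.var()  # beats the mean predictor
        yhat = model.predict_table(test)
        assert np.mean((yhat - test.target) ** 2) < test.target.var()

    def test_training_is_deterministic(self, schema):
        train, valid, _ = planted_tables(schema, n=300, seed=6)
        part = MaskUnitPartition.from_schema(schema)
        logs = []
        for _ in range(2):
            model = GroupMaskedTabNet(schema, part, tiny_config(
                max_epochs=3, seed=6))
            logs.append(model.fit(train, valid))
        assert logs[0] == logs[1]

    def test_empty_split_rejected(self, schema):
        train, valid, _ = planted_tables(schema, n=100, seed=1)
        empty = valid.take(np.array([], dtype=int))
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config(max_epochs=1))
        with pytest.raises(DataError):
            model.fit(train, empty)

    def test_save_load_round_trip(self, schema, tmp_path):
        train, valid, test = planted_tables(schema, n=300, seed=8)
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config(max_epochs=2, seed=8))
        model.fit(train, valid)
        prefix = str(tmp_path / "model")
        model.save(prefix)
        loaded = GroupMaskedTabNet.load(prefix)
        np.testing.assert_allclose(
            model.predict_table(test), loaded.predict_table(test), atol=1e-12
        )


class TestExplain:
    def test_unit_importances_sum_to_one_nonnegative(self, schema):
        part = MaskUnitPartition.from_schema(schema)
        model = GroupMaskedTabNet(schema, part, tiny_config(seed=9))
        _, unit_importance = model.explain(random_input(schema, seed=9))
        vals = np.array(list(unit_importance.values()))
        assert (vals >= 0).all()
        assert vals.sum() == pytest.approx(1.0, abs=1e-6)
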