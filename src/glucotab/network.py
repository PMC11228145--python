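"""Group-masked attentive tabular network.

A sequential multi-step regressor in the attentive-tabular-network family:
at every decision step an attentive transformer produces a sparse attention
distribution over *mask units* — either single columns or whole clinical
groups sharing one attention value — conditioned on a multiplicative prior
that discourages re-selecting already-attended units; a GLU feature
transformer (shared + step-specific blocks, ghost batch norm, residual
scaling by sqrt(1/2)) turns the masked input into a decision vector, and the
rectified decisions accumulate into the final prediction.

Attention is computed as the Euclidean projection of the prior-scaled scores
onto the capped simplex {0 <= q <= min(prior, 1), sum q = 1}.  Whenever no
cap binds this is exactly sparsemax of prior * scores; the cap additionally
guarantees the telescoping budget property: with relaxation gamma = 1 a
unit's cumulative attention across steps never exceeds 1, and a fully
attended unit is never re-selected.

Feature importance: the per-step mask M[i] broadcasts each unit's attention
to its member columns; the aggregate importance M_agg is the per-sample
eta-weighted sum of the M[i] (eta = total rectified decision magnitude of
the step), row-normalised to 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import (
    Adam,
    Tensor,
    capped_sparsemax,
    concat_rows,
    sparsemax_np,
)
from .errors import DataError, ParameterError, SchemaError, TrainingError
from .schema import ClinicalTable, FeatureSchema

EPS_ENTROPY = 1e-15
BN_EPS = 1e-5
BN_MOMENTUM = 0.1  # fraction of the batch statistic mixed into running stats


def sparsemax(scores: np.ndarray) -> np.ndarray:
    """Euclidean projection of a score vector (or rows of a matrix) onto the
    probability simplex; the output sums to 1 and may contain exact zeros."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("sparsemax requires finite scores")
    if scores.ndim == 1:
        return sparsemax_np(scores[None, :])[0]
    return sparsemax_np(scores)


# ---------------------------------------------------------------------------
# Mask-unit partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskUnitPartition:
    """Partition of the model-input columns into attention units."""

    units: tuple[tuple[str, tuple[int, ...]], ...]
    n_columns: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for uid, members in self.units:
            if not members:
                raise SchemaError(f"unit {uid!r} is empty")
            for j in members:
                if j in seen:
                    raise SchemaError(f"column {j} assigned to two units")
                seen.add(j)
        if seen != set(range(self.n_columns)):
            raise SchemaError("units do not partition the model-input columns")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return tuple(uid for uid, _ in self.units)

    def membership(self) -> np.ndarray:
        """Unit x column binary matrix G with G[u, j] = 1 iff j in unit u."""
        G = np.zeros((len(self.units), self.n_columns))
        for u, (_, members) in enumerate(self.units):
            G[u, list(members)] = 1.0
        return G

    @classmethod
    def singletons(cls, n_columns: int, ids=None) -> "MaskUnitPartition":
        ids = ids or [f"col{j}" for j in range(n_columns)]
        return cls(tuple((str(ids[j]), (j,)) for j in range(n_columns)), n_columns)

    @classmethod
    def from_schema(
        cls,
        schema: FeatureSchema,
        masked_groups: tuple[str, ...] = ("B", "D"),
        mask_grp_blocks: bool = True,
    ) -> "MaskUnitPartition":
        """Default partition: each masked clinical group is one unit, each
        appended ``_grp`` block is one unit, everything else a singleton."""
        units: dict[str, list[int]] = {}
        order: list[str] = []
        for j, a in enumerate(schema.attributes):
            g = a.group_id
            grouped = g in masked_groups or (mask_grp_blocks and g.endswith("_grp"))
            key = g if grouped else a.attribute_id
            if key not in units:
                units[key] = []
                order.append(key)
            units[key].append(j)
        return cls(
            tuple((k, tuple(units[k])) for k in order), schema.n_attributes
        )


@dataclass
class TabNetConfig:
    n_steps: int = 4
    n_d: int = 16
    n_a: int = 16
    gamma: float = 1.5
    lambda_sparse: float = 1e-4
    n_shared: int = 2
    n_independent: int = 2
    virtual_batch: int = 128
    batch: int = 256
    lr: float = 2e-2
    max_epochs: int = 200
    patience: int = 30
    mask_mode: str = "broadcast"  # or "split": unit mass divided over members
    seed: int = 0

    def validate(self) -> None:
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")
        if self.gamma < 1:
            raise ParameterError("gamma must be >= 1")
        for name in ("n_d", "n_a", "n_shared", "n_independent", "batch",
                     "virtual_batch", "max_epochs"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if self.mask_mode not in ("broadcast", "split"):
            raise ParameterError(f"unknown mask_mode {self.mask_mode!r}")


@dataclass
class StepTrace:
    """Per-step attention tensors plus the aggregate importance matrix."""

    unit_attention: list[np.ndarray]   # q[i]: batch x units
    feature_masks: list[np.ndarray]    # M[i]: batch x columns
    priors: list[np.ndarray]           # P[i]: batch x units (P[0] = ones)
    step_strength: list[np.ndarray]    # eta[i]: batch
    aggregate_importance: np.ndarray   # M_agg: batch x columns, rows sum to 1


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _BatchNorm:
    """Batch norm with running statistics; ghost mode normalises fixed-size
    virtual sub-batches with their own statistics during training."""

    def __init__(self, dim: int, virtual_batch: int | None = None):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.virtual_batch = virtual_batch

    @property
    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def _normalize_chunk(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
        self.running_mean = (1 - BN_MOMENTUM) * self.running_mean + \
            BN_MOMENTUM * mu.data.ravel()
        self.running_var = (1 - BN_MOMENTUM) * self.running_var + \
            BN_MOMENTUM * var.data.ravel()
        return (x - mu) * ((var + BN_EPS) ** -0.5)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if not training:
            xn = (x - self.running_mean) * ((self.running_var + BN_EPS) ** -0.5)
            return xn * self.gamma + self.beta
        vb = self.virtual_batch
        n = x.shape[0]
        if vb is None or n <= vb:
            xn = self._normalize_chunk(x)
        else:
            chunks = []
            for start in range(0, n, vb):
                chunks.append(self._normalize_chunk(x.rows(start, min(start + vb, n))))
            xn = concat_rows(chunks)
        return xn * self.gamma + self.beta


class _GLUBlock:
    """affine -> ghost BN -> gated linear unit."""

    def __init__(self, n_in: int, n_out: int, virtual_batch: int,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + 2 * n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, 2 * n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(2 * n_out), requires_grad=True)
        self.bn = _BatchNorm(2 * n_out, virtual_batch)
        self.n_out = n_out

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b] + self.bn.params

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        y = self.bn(x @ self.W + self.b, training)
        return y.cols(0, self.n_out) * y.cols(self.n_out, 2 * self.n_out).sigmoid()


SQRT_HALF = float(np.sqrt(0.5))


class GroupMaskedTabNet:
    """The regressor; see the module docstring for the architecture."""

    def __init__(self, schema: FeatureSchema, partition: MaskUnitPartition,
                 config: TabNetConfig):
        config.validate()
        if partition.n_columns != schema.n_attributes:
            raise SchemaError("partition does not match the schema width")
        self.schema = schema
        self.partition = partition
        self.config = config
        self.column_ids = schema.attribute_ids
        self.categorical_cols = tuple(
            schema.index_of(a) for a in schema.categorical_ids()
        )
        self._G = partition.membership()
        if config.mask_mode == "split":
            self._G = self._G / self._G.sum(axis=1, keepdims=True)

        rng = np.random.default_rng(config.seed)
        p = schema.n_attributes
        h = config.n_d + config.n_a

        # one scalar embedding per binary categorical column
        self.embeddings = {
            j: Tensor(rng.normal(0.0, 0.01, size=(2, 1)), requires_grad=True)
            for j in self.categorical_cols
        }
        self.input_bn = _BatchNorm(p)

        vb = config.virtual_batch
        self.shared: list[_GLUBlock] = []
        for k in range(config.n_shared):
            n_in = p if k == 0 else h
            self.shared.append(_GLUBlock(n_in, h, vb, rng))
        # step-specific blocks; set 0 belongs to the initial splitter
        self.independent: list[list[_GLUBlock]] = [
            [_GLUBlock(h, h, vb, rng) for _ in range(config.n_independent)]
            for _ in range(config.n_steps + 1)
        ]
        U = partition.n_units
        self.att_W: list[Tensor] = []
        self.att_b: list[Tensor] = []
        self.att_bn: list[_BatchNorm] = []
        limit = np.sqrt(6.0 / (config.n_a + U))
        for _ in range(config.n_steps):
            self.att_W.append(Tensor(rng.uniform(-limit, limit, size=(config.n_a, U)),
                                     requires_grad=True))
            self.att_b.append(Tensor(np.zeros(U), requires_grad=True))
            self.att_bn.append(_BatchNorm(U, vb))
        lim_out = np.sqrt(6.0 / (config.n_d + 1))
        self.W_out = Tensor(rng.uniform(-lim_out, lim_out, size=(config.n_d, 1)),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(1), requires_grad=True)

        self.fitted = False
        self.training_log: list[dict] = []

    # -- parameters -----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = list(self.embeddings.values())
        params += self.input_bn.params
        for blk in self.shared:
            params += blk.params
        for step_blocks in self.independent:
            for blk in step_blocks:
                params += blk.params
        for W, b, bn in zip(self.att_W, self.att_b, self.att_bn):
            params += [W, b] + bn.params
        params += [self.W_out, self.b_out]
        return params

    # -- forward pieces -------------------------------------------------
    def _embed(self, x: np.ndarray) -> Tensor:
        base = x.copy()
        contributions = []
        for j, emb in self.embeddings.items():
            onehot = np.zeros((len(x), 2))
            codes = np.clip(x[:, j], 0, 1).astype(int)
            onehot[np.arange(len(x)), codes] = 1.0
            base[:, j] = 0.0
            selector = np.zeros((1, x.shape[1]))
            selector[0, j] = 1.0
            contributions.append((Tensor(onehot) @ emb) @ Tensor(selector))
        out = Tensor(base)
        for c in contributions:
            out = out + c
        return out

    def _transform(self, x: Tensor, step_set: int, training: bool) -> Tensor:
        h = None
        for k, blk in enumerate(self.shared):
            y = blk(x if k == 0 else h, training)
            h = y if k == 0 else (y + h) * SQRT_HALF
        for blk in self.independent[step_set]:
            h = (blk(h, training) + h) * SQRT_HALF
        return h

    def _attentive_step(self, a_prev: Tensor, prior: Tensor, step: int,
                        training: bool):
        """q = capped projection of prior * scores; M = q . G;
        prior_out = prior * (gamma - q)."""
        if (prior.data < -1e-12).any():
            raise DataError("prior must be elementwise nonnegative")
        scores = self.att_bn[step](a_prev @ self.att_W[step] + self.att_b[step],
                                   training)
        cap = np.minimum(prior.data, 1.0)
        q = capped_sparsemax(prior * scores, cap)
        M = q @ Tensor(self._G)
        prior_out = prior * ((-q) + self.config.gamma)
        return q, M, prior_out

    def forward(self, x: np.ndarray, training: bool = False):
        """Full pass; returns (prediction Tensor, StepTrace, sparsity Tensor)."""
        x = np.asarray(x, dtype=float)
        if np.isnan(x).any():
            raise DataError("forward requires a complete matrix (no missing cells)")
        if x.shape[1] != self.partition.n_columns:
            raise SchemaError("input width does not match the model")
        cfg = self.config
        n = len(x)

        x_bn = self.input_bn(self._embed(x), training)
        feat = self._transform(x_bn, 0, training)
        a = feat.cols(cfg.n_d, cfg.n_d + cfg.n_a)

        prior = Tensor(np.ones((n, self.partition.n_units)))
        priors = [prior.data.copy()]
        qs, Ms, etas = [], [], []
        d_sum = None
        sparsity = None
        agg = np.zeros((n, self.partition.n_columns))
        for i in range(cfg.n_steps):
            q, M, prior = self._attentive_step(a, prior, i, training)
            feat = self._transform(M * x_bn, i + 1, training)
            d = feat.cols(0, cfg.n_d).relu()
            a = feat.cols(cfg.n_d, cfg.n_d + cfg.n_a)
            d_sum = d if d_sum is None else d_sum + d
            ent = -(q * (q + EPS_ENTROPY).log()).sum(axis=1).mean()
            sparsity = ent if sparsity is None else sparsity + ent
            eta = d.data.sum(axis=1)
            qs.append(q.data.copy())
            Ms.append(M.data.copy())
            priors.append(prior.data.copy())
            etas.append(eta)
            agg += eta[:, None] * M.data
        pred = d_sum @ self.W_out + self.b_out
        sparsity = sparsity * (1.0 / cfg.n_steps)

        rowsum = agg.sum(axis=1, keepdims=True)
        flat = rowsum.ravel() <= 0
        agg[flat] = 1.0 / self.partition.n_columns
        rowsum[flat] = 1.0
        trace = StepTrace(
            unit_attention=qs,
            feature_masks=Ms,
            priors=priors,
            step_strength=etas,
            aggregate_importance=agg / rowsum,
        )
        return pred, trace, sparsity

    # -- training -------------------------------------------------------
    def _matrix(self, table: ClinicalTable) -> tuple[np.ndarray, np.ndarray]:
        if not table.is_complete:
            raise DataError("network input table has unobserved cells")
        if table.target is None:
            raise DataError("network fitting requires a target column")
        if tuple(table.schema.attribute_ids) != tuple(self.column_ids):
            raise SchemaError("table columns do not match the fitted model")
        return table.values, table.target

    def fit(self, train: ClinicalTable, valid: ClinicalTable) -> list[dict]:
        """Minimise MSE + lambda_sparse * sparsity with Adam; track validation
        MSE per epoch and restore the peak-validation parameters."""
        cfg = self.config
        X, y = self._matrix(train)
        Xv, yv = self._matrix(valid)
        if len(X) == 0 or len(Xv) == 0:
            raise DataError("empty training or validation split")

        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(self.parameters(), lr=cfg.lr)
        best_val = np.inf
        best_state: list[np.ndarray] | None = None
        best_stats: list[tuple[np.ndarray, np.ndarray]] | None = None
        stall = 0
        self.training_log = []

        def bn_layers():
            out = [self.input_bn]
            out += [blk.bn for blk in self.shared]
            for step_blocks in self.independent:
                out += [blk.bn for blk in step_blocks]
            out += list(self.att_bn)
            return out

        for epoch in range(cfg.max_epochs):
            lr = cfg.lr * (0.9 ** (epoch // 10))
            perm = rng.permutation(len(X))
            losses, mses, ents = [], [], []
            for start in range(0, len(X), cfg.batch):
                idx = perm[start:start + cfg.batch]
                if len(idx) < 2:
                    continue  # BN needs more than one row
                pred, _, sparsity = self.forward(X[idx], training=True)
                err = pred - Tensor(y[idx][:, None])
                mse = (err ** 2.0).mean()
                loss = mse + sparsity * cfg.lambda_sparse
                if not np.isfinite(loss.data):
                    raise TrainingError(f"divergent loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step(lr=lr)
                losses.append(float(loss.data))
                mses.append(float(mse.data))
                ents.append(float(sparsity.data))
            val_mse = float(np.mean((self.predict(Xv) - yv) ** 2))
            self.training_log.append({
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_mse": float(np.mean(mses)),
                "sparsity": float(np.mean(ents)),
                "val_mse": val_mse,
                "lr": lr,
            })
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_state = [p.data.copy() for p in self.parameters()]
                best_stats = [(b.running_mean.copy(), b.running_var.copy())
                              for b in bn_layers()]
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        if best_state is not None:
            for p, saved in zip(self.parameters(), best_state):
                p.data = saved
            for b, (m, v) in zip(bn_layers(), best_stats):
                b.running_mean, b.running_var = m, v
        self.fitted = True
        return self.training_log

    def predict(self, X: np.ndarray) -> np.ndarray:
        pred, _, _ = self.forward(np.asarray(X, dtype=float), training=False)
        return pred.data.ravel()

    def predict_table(self, table: ClinicalTable) -> np.ndarray:
        if not table.is_complete:
            raise DataError("prediction requires a complete table")
        return self.predict(table.values)

    def explain(self, X: np.ndarray):
        """Per-step masks, aggregate importance and per-unit importance mass
        (mean M_agg summed over each unit's member columns; sums to 1)."""
        _, trace, _ = self.forward(np.asarray(X, dtype=float), training=False)
        col_mean = trace.aggregate_importance.mean(axis=0)
        unit_importance = {
            uid: float(col_mean[list(members)].sum())
            for uid, members in self.partition.units
        }
        return trace, unit_importance

    # -- serialisation --------------------------------------------------
    def save(self, prefix: str) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        stats = {}
        for i, bn in enumerate(self._all_bn()):
            stats[f"bn{i}_mean"] = bn.running_mean
            stats[f"bn{i}_var"] = bn.running_var
        np.savez(prefix + ".npz", **arrays, **stats)
        sidecar = {
            "config": asdict(self.config),
            "units": [[uid, list(members)] for uid, members in self.partition.units],
            "n_columns": self.partition.n_columns,
            "column_ids": list(self.column_ids),
            "schema": {
                "target_name": self.schema.target_name,
                "attributes": [
                    [a.attribute_id, a.name, a.group_id, a.kind]
                    for a in self.schema.attributes
                ],
            },
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    def _all_bn(self) -> list[_BatchNorm]:
        out = [self.input_bn] + [blk.bn for blk in self.shared]
        for step_blocks in self.independent:
            out += [blk.bn for blk in step_blocks]
        return out + list(self.att_bn)

    @classmethod
    def load(cls, prefix: str) -> "GroupMaskedTabNet":
        from .schema import Attribute

        with open(prefix + ".json") as fh:
            sidecar = json.load(fh)
        schema = FeatureSchema(
            tuple(Attribute(*a) for a in sidecar["schema"]["attributes"]),
            sidecar["schema"]["target_name"],
        )
        partition = MaskUnitPartition(
            tuple((uid, tuple(members)) for uid, members in sidecar["units"]),
            sidecar["n_columns"],
        )
        model = cls(schema, partition, TabNetConfig(**sidecar["config"]))
        data = np.load(prefix + ".npz")
        for i, p in enumerate(model.parameters()):
            p.data = data[f"p{i}"]
        for i, bn in enumerate(model._all_bn()):
            bn.running_mean = data[f"bn{i}_mean"]
            bn.running_var = data[f"bn{i}_var"]
        model.fitted = True
        return model
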