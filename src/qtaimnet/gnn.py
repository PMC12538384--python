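"""Message-passing neural network over molecular heterographs.

Architecture: per-node-type linear embedding to a fixed width, R rounds of
typed message passing (each node type aggregates mean-pooled learned
transforms of its typed neighbors — bond nodes from their two atoms, atom
nodes from incident bonds, both from/to the global node), then graph-level
pooling of atom and bond embeddings concatenated with the global state, and a
fully-connected readout producing one value per target.

All aggregations are permutation-invariant, so predictions are invariant to
atom relabeling.  Training minimizes mean squared error on z-scored targets
with Adam and early stopping on validation loss; metrics are always reported
on de-standardized labels.

Graphs are packed into batches as block sparse aggregation matrices, so a
whole batch is one chain of (sparse) matrix products through the in-package
autodiff.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp

from . import autodiff as ad
from .graphs import GraphRecord, SchemaMismatchError

POOLINGS = ("mean", "attention")

#: 1 kcal/mol in eV — conventional "chemical accuracy" width for EwT.
DEFAULT_EWT_THRESHOLD = 0.0434


@dataclass
class ModelConfig:
    hidden: int = 32
    rounds: int = 1
    pooling: str = "mean"
    readout_hidden: tuple[int, ...] = (32,)
    lr: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 50
    seed: int = 0
    targets: tuple[str, ...] = ("y",)
    ewt_threshold: float = DEFAULT_EWT_THRESHOLD

    def __post_init__(self) -> None:
        if self.pooling not in POOLINGS:
            raise ValueError(f"pooling must be one of {POOLINGS}")
        for name in ("hidden", "readout_hidden", "lr", "batch_size", "max_epochs"):
            v = getattr(self, name)
            vals = v if isinstance(v, tuple) else (v,)
            if any(x <= 0 for x in vals):
                raise ValueError(f"{name} must be positive")


@dataclass
class Metrics:
    mae: float
    rmse: float
    r2: float
    ewt_pct: float
    n: int

    def to_dict(self) -> dict:
        return {"MAE": self.mae, "RMSE": self.rmse, "R2": self.r2,
                "EwT_pct": self.ewt_pct, "n": self.n}


def compute_metrics(y_true, y_pred, ewt_threshold=DEFAULT_EWT_THRESHOLD) -> Metrics:
    """MAE, RMSE, R^2 and percent-within-threshold on raw-scale labels.

    R^2 is NaN (undefined) when the labels have zero variance.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("metrics require at least one record")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / sstot if sstot > 0 else math.nan
    ewt = 100.0 * float(np.mean(np.abs(err) <= ewt_threshold))
    return Metrics(mae=mae, rmse=rmse, r2=r2, ewt_pct=ewt, n=y_true.size)


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

class GraphBatch:
    """A set of heterographs packed as stacked features + sparse aggregators."""

    def __init__(self, records: list[GraphRecord], targets: tuple[str, ...]):
        self.ids = [r.id for r in records]
        g = len(records)
        atom_feats, bond_feats, glob_feats = [], [], []
        ab_rows, ab_cols = [], []  # atom <- bond incidence
        atom_graph, bond_graph = [], []
        a_off = b_off = 0
        for gi, rec in enumerate(records):
            graph = rec.graph
            atom_feats.append(graph.features["atom"])
            bond_feats.append(graph.features["bond"])
            glob_feats.append(graph.features["global"])
            for bi, (i, j) in enumerate(graph.bond_endpoints):
                ab_rows += [a_off + int(i), a_off + int(j)]
                ab_cols += [b_off + bi, b_off + bi]
            atom_graph += [gi] * graph.n_atoms
            bond_graph += [gi] * graph.n_bonds
            a_off += graph.n_atoms
            b_off += graph.n_bonds
        self.x_atom = np.vstack(atom_feats)
        self.x_bond = np.vstack(bond_feats) if b_off else np.zeros(
            (0, records[0].graph.features["bond"].shape[1])
        )
        self.x_global = np.vstack(glob_feats)
        na, nb = a_off, b_off
        self.n_graphs = g
        atom_graph = np.asarray(atom_graph, dtype=int)
        bond_graph = np.asarray(bond_graph, dtype=int)

        inc = sp.csr_matrix(
            (np.ones(len(ab_rows)), (ab_rows, ab_cols)), shape=(na, nb)
        )
        atom_deg = np.asarray(inc.sum(axis=1)).ravel()
        atom_deg[atom_deg == 0] = 1.0
        self.agg_atom_from_bond = sp.diags(1.0 / atom_deg) @ inc  # mean over incident bonds
        self.agg_bond_from_atom = (0.5 * inc.T).tocsr()  # mean over the 2 endpoints

        ones_a = np.ones(na)
        pga = sp.csr_matrix((ones_a, (atom_graph, np.arange(na))), shape=(g, na))
        a_per_g = np.asarray(pga.sum(axis=1)).ravel()
        self.pool_atom_sum = pga
        self.pool_atom_mean = sp.diags(1.0 / np.maximum(a_per_g, 1.0)) @ pga
        self.bcast_atom = pga.T.tocsr()  # atom <- its graph's global

        ones_b = np.ones(nb)
        pgb = sp.csr_matrix((ones_b, (bond_graph, np.arange(nb))), shape=(g, nb))
        b_per_g = np.asarray(pgb.sum(axis=1)).ravel()
        self.pool_bond_sum = pgb
        self.pool_bond_mean = sp.diags(1.0 / np.maximum(b_per_g, 1.0)) @ pgb
        self.bcast_bond = pgb.T.tocsr()

        self.bond_graph = bond_graph
        self.atom_graph = atom_graph
        if targets:
            self.y = np.array(
                [[rec.labels[t] for t in targets] for rec in records], dtype=float
            )
        else:
            self.y = np.zeros((g, 0))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class HeteroMPNN:
    """Parameters + forward pass; weights live in a flat name->Tensor dict."""

    def __init__(self, config: ModelConfig, feature_dims: dict[str, int],
                 schema_hash: str = ""):
        self.config = config
        self.feature_dims = dict(feature_dims)
        self.schema_hash = schema_hash
        self.params: dict[str, ad.Tensor] = {}
        rng = np.random.default_rng(config.seed)
        h = config.hidden

        def init(name, fan_in, fan_out):
            scale = math.sqrt(2.0 / max(fan_in, 1))
            self.params[name] = ad.parameter(rng.normal(0.0, scale, (fan_in, fan_out)))
            self.params[name + "_b"] = ad.parameter(np.zeros((1, fan_out)))

        for nt in ("atom", "bond", "global"):
            init(f"embed_{nt}", feature_dims[nt], h)
        for r in range(config.rounds):
            for dst, srcs in (("atom", ("self", "bond", "global")),
                              ("bond", ("self", "atom", "global")),
                              ("global", ("self", "atom", "bond"))):
                for src in srcs:
                    init(f"mp{r}_{dst}_{src}", h, h)
        if config.pooling == "attention":
            for nt in ("atom", "bond"):
                self.params[f"attn_{nt}"] = ad.parameter(
                    rng.normal(0.0, 1.0 / math.sqrt(h), (h, 1))
                )
        width = 3 * h
        # linear skip from the pooled representation straight to the output:
        # gives the readout an exact linear pathway alongside the MLP
        init("read_skip", width, len(config.targets))
        for li, hw in enumerate(config.readout_hidden):
            init(f"read{li}", width, hw)
            width = hw
        init("read_out", width, len(config.targets))

    def parameters(self) -> list[ad.Tensor]:
        return list(self.params.values())

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.value.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].value = v.copy()

    def _dense(self, name, x):
        return ad.matmul(x, self.params[name]) + self.params[name + "_b"]

    def _attention_pool(self, batch, h_nodes, pool_sum, bcast, attn_name):
        scores = ad.matmul(h_nodes, self.params[attn_name])  # (N,1)
        # softmax within each graph; the per-graph max shift is exact
        # (softmax is shift-invariant, so treating it as constant is correct)
        if scores.value.shape[0] == 0:
            return ad.spmm(pool_sum, h_nodes)
        graph_max = np.full((pool_sum.shape[0], 1), -np.inf)
        np.maximum.at(graph_max[:, 0], self._graph_index(batch, attn_name), scores.value[:, 0])
        graph_max[~np.isfinite(graph_max)] = 0.0
        e = ad.exp(scores - ad.constant(bcast @ graph_max))
        denom = ad.spmm(pool_sum, e) + ad.constant(1e-12)
        w = e / ad.spmm(bcast, denom)
        return ad.spmm(pool_sum, ad.mul(w, h_nodes))

    @staticmethod
    def _graph_index(batch, attn_name):
        return batch.atom_graph if attn_name.endswith("atom") else batch.bond_graph

    def forward(self, batch: GraphBatch) -> ad.Tensor:
        cfg = self.config
        # embeddings are linear so that mean pooling of the embedded features
        # preserves an exact linear image of the raw feature means
        h = {
            "atom": self._dense("embed_atom", ad.constant(batch.x_atom)),
            "bond": self._dense("embed_bond", ad.constant(batch.x_bond)),
            "global": self._dense("embed_global", ad.constant(batch.x_global)),
        }
        # residual updates: each round adds a relu-gated typed-message term,
        # keeping a linear path from embeddings to the pooled representation
        for r in range(cfg.rounds):
            new_atom = h["atom"] + ad.relu(
                self._dense(f"mp{r}_atom_self", h["atom"])
                + ad.matmul(ad.spmm(batch.agg_atom_from_bond, h["bond"]),
                            self.params[f"mp{r}_atom_bond"])
                + ad.matmul(ad.spmm(batch.bcast_atom, h["global"]),
                            self.params[f"mp{r}_atom_global"])
            )
            new_bond = h["bond"] + ad.relu(
                self._dense(f"mp{r}_bond_self", h["bond"])
                + ad.matmul(ad.spmm(batch.agg_bond_from_atom, h["atom"]),
                            self.params[f"mp{r}_bond_atom"])
                + ad.matmul(ad.spmm(batch.bcast_bond, h["global"]),
                            self.params[f"mp{r}_bond_global"])
            )
            new_global = h["global"] + ad.relu(
                self._dense(f"mp{r}_global_self", h["global"])
                + ad.matmul(ad.spmm(batch.pool_atom_mean, h["atom"]),
                            self.params[f"mp{r}_global_atom"])
                + ad.matmul(ad.spmm(batch.pool_bond_mean, h["bond"]),
                            self.params[f"mp{r}_global_bond"])
            )
            h = {"atom": new_atom, "bond": new_bond, "global": new_global}

        if cfg.pooling == "mean":
            pooled_atom = ad.spmm(batch.pool_atom_mean, h["atom"])
            pooled_bond = ad.spmm(batch.pool_bond_mean, h["bond"])
        else:
            pooled_atom = self._attention_pool(
                batch, h["atom"], batch.pool_atom_sum, batch.bcast_atom, "attn_atom")
            pooled_bond = self._attention_pool(
                batch, h["bond"], batch.pool_bond_sum, batch.bcast_bond, "attn_bond")
        z = ad.concat([pooled_atom, pooled_bond, h["global"]], axis=1)
        skip = self._dense("read_skip", z)
        for li in range(len(cfg.readout_hidden)):
            z = ad.relu(self._dense(f"read{li}", z))
        return self._dense("read_out", z) + skip


@dataclass
class TrainedModel:
    model: HeteroMPNN
    config: ModelConfig
    label_mean: np.ndarray
    label_std: np.ndarray
    history: list[dict] = field(default_factory=list)
    best_val_loss: float = math.inf

    def predict(self, records: list[GraphRecord]) -> np.ndarray:
        """De-standardized predictions, shape (n_records, n_targets)."""
        for r in records:
            if self.model.schema_hash and r.schema_hash != self.model.schema_hash:
                raise SchemaMismatchError(
                    f"record {r.id} schema {r.schema_hash} != model {self.model.schema_hash}"
                )
        batch = GraphBatch(records, self.config.targets)
        z = self.model.forward(batch).value
        return z * self.label_std + self.label_mean


class TrainingDivergedError(RuntimeError):
    pass


def _mse_loss(model, batch, y_std):
    pred = model.forward(batch)
    diff = pred - ad.constant(y_std)
    return ad.mean(ad.mul(diff, diff))


def train(
    config: ModelConfig,
    train_records: list[GraphRecord],
    val_records: list[GraphRecord],
) -> TrainedModel:
    """Fit with Adam on standardized-target MSE; early stop on validation loss."""
    if not val_records:
        raise ValueError("at least one validation record is required")
    ids = {r.id for r in train_records} | {r.id for r in val_records}
    if len(ids) != len(train_records) + len(val_records):
        raise ValueError("train and validation ids must be disjoint")
    targets = config.targets
    y_train = np.array([[r.labels[t] for t in targets] for r in train_records])
    label_mean = y_train.mean(axis=0)
    label_std = y_train.std(axis=0)
    label_std[label_std == 0] = 1.0

    feature_dims = {nt: train_records[0].graph.features[nt].shape[1]
                    for nt in ("atom", "bond", "global")}
    model = HeteroMPNN(config, feature_dims, schema_hash=train_records[0].schema_hash)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(train_records))
    batches = []
    for lo in range(0, len(order), config.batch_size):
        chunk = [train_records[i] for i in order[lo : lo + config.batch_size]]
        b = GraphBatch(chunk, targets)
        batches.append((b, (b.y - label_mean) / label_std))
    val_batch = GraphBatch(val_records, targets)
    val_y = (val_batch.y - label_mean) / label_std

    opt = ad.Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    best_state = model.state()
    best_val = math.inf
    since_best = 0
    history = []
    for epoch in range(config.max_epochs):
        train_loss = 0.0
        for batch, y_std in batches:
            opt.zero_grad()
            loss = _mse_loss(model, batch, y_std)
            if not np.isfinite(loss.value):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            train_loss += float(loss.value) * len(batch.ids)
        train_loss /= len(train_records)
        val_loss = float(_mse_loss(model, val_batch, val_y).value)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    model.load_state(best_state)
    return TrainedModel(
        model=model, config=config, label_mean=label_mean, label_std=label_std,
        history=history, best_val_loss=best_val,
    )


def evaluate(
    trained: TrainedModel,
    records: list[GraphRecord],
    ewt_threshold: float | None = None,
) -> dict[str, Metrics]:
    """Per-target metrics on de-standardized labels."""
    if not records:
        raise ValueError("evaluate requires at least one record")
    threshold = trained.config.ewt_threshold if ewt_threshold is None else ewt_threshold
    pred = trained.predict(records)
    out = {}
    for ti, t in enumerate(trained.config.targets):
        y = np.array([r.labels[t] for r in records])
        out[t] = compute_metrics(y, pred[:, ti], threshold)
    return out
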