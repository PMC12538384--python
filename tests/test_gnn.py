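import math

import numpy as np
import pytest

from qtaimnet.gnn import (
    GraphBatch,
    HeteroMPNN,
    ModelConfig,
    compute_metrics,
    evaluate,
    train,
)
from qtaimnet.graphs import GraphRecord, HeteroGraph


def _graph(atom, bond, glob, endpoints):
    return HeteroGraph(
        features={
            "atom": np.asarray(atom, float),
            "bond": np.asarray(bond, float).reshape(len(bond), -1)
            if len(bond) else np.zeros((0, 2)),
            "global": np.asarray([glob], float),
        },
        bond_endpoints=np.asarray(endpoints, int).reshape(len(endpoints), 2),
    )


def _rec(i, graph, y=0.0):
    return GraphRecord(id=f"g{i}", graph=graph, labels={"y": y}, schema_hash="h")


@pytest.fixture
def toy_records():
    rng = np.random.default_rng(0)
    recs = []
    for i in range(6):
        n = 3 + i % 2
        atoms = rng.normal(size=(n, 4))
        bonds = rng.normal(size=(n - 1, 2))
        endpoints = [(j, j + 1) for j in range(n - 1)]
        recs.append(_rec(i, _graph(atoms, bonds, rng.normal(size=3), endpoints),
                         y=float(rng.normal())))
    return recs


# -- metrics ---------------------------------------------------------------

def test_metrics_perfect_prediction():
    m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (m.mae, m.rmse, m.r2, m.ewt_pct) == (0.0, 0.0, 1.0, 100.0)


def test_metrics_mean_predictor_r2_zero():
    y = np.array([1.0, 2.0, 3.0, 6.0])
    m = compute_metrics(y, np.full(4, y.mean()))
    assert m.r2 == pytest.approx(0.0, abs=1e-12)


def test_metrics_hand_example():
    """y=(0,0,0,0), yhat=(1,-1,2,0), threshold 1: MAE 1, RMSE sqrt(1.5), EwT 75%."""
    m = compute_metrics([0, 0, 0, 0], [1, -1, 2, 0], ewt_threshold=1.0)
    assert m.mae == pytest.approx(1.0)
    assert m.rmse == pytest.approx(math.sqrt(1.5))
    assert m.ewt_pct == pytest.approx(75.0)


def test_metrics_zero_variance_r2_nan():
    m = compute_metrics([2.0, 2.0], [1.0, 3.0])
    assert math.isnan(m.r2)


def test_metrics_match_streaming_oracle():
    """Independent one-pass (streaming) accumulation agrees to 1e-10."""
    rng = np.random.default_rng(3)
    y = rng.normal(size=500)
    yhat = y + rng.normal(scale=0.3, size=500)
    m = compute_metrics(y, yhat, ewt_threshold=0.2)
    n = s_abs = s_sq = s_y = s_yy = within = 0
    for a, b in zip(y, yhat):
        n += 1
        s_abs += abs(b - a)
        s_sq += (b - a) ** 2
        s_y += a
        s_yy += a * a
        within += abs(b - a) <= 0.2
    assert abs(m.mae - s_abs / n) < 1e-10
    assert abs(m.rmse - math.sqrt(s_sq / n)) < 1e-10
    sstot = s_yy - s_y**2 / n
    assert abs(m.r2 - (1 - s_sq / sstot)) < 1e-10
    assert abs(m.ewt_pct - 100 * within / n) < 1e-10


# -- forward properties -----------------------------------------------------

@pytest.mark.parametrize("pooling", ["mean", "attention"])
def test_forward_permutation_invariance(pooling):
    rng = np.random.default_rng(1)
    atoms = rng.normal(size=(5, 4))
    bonds = rng.normal(size=(3, 2))
    endpoints = [(0, 1), (1, 2), (3, 4)]
    g1 = _graph(atoms, bonds, [1.0, 0.0, 2.0], endpoints)
    perm = [4, 2, 0, 3, 1]
    inv = np.argsort(perm)
    g2 = _graph(atoms[perm], bonds, [1.0, 0.0, 2.0],
                [tuple(sorted((inv[i], inv[j]))) for i, j in endpoints])
    cfg = ModelConfig(hidden=8, rounds=2, pooling=pooling, seed=0)
    model = HeteroMPNN(cfg, {"atom": 4, "bond": 2, "global": 3})
    p1 = model.forward(GraphBatch([_rec(0, g1)], ("y",))).value
    p2 = model.forward(GraphBatch([_rec(0, g2)], ("y",))).value
    assert np.abs(p1 - p2).max() < 1e-6


def test_zero_rounds_is_a_set_model():
    """With no message passing and mean pooling, only feature multisets matter
    — connectivity is invisible."""
    rng = np.random.default_rng(2)
    atoms = rng.normal(size=(4, 4))
    bonds = rng.normal(size=(2, 2))
    g_chain = _graph(atoms, bonds, [0.0, 1.0, 0.0], [(0, 1), (1, 2)])
    g_other = _graph(atoms, bonds, [0.0, 1.0, 0.0], [(0, 3), (2, 3)])
    cfg = ModelConfig(hidden=8, rounds=2, seed=0)
    model = HeteroMPNN(cfg, {"atom": 4, "bond": 2, "global": 3})
    with_mp = [
        model.forward(GraphBatch([_rec(0, g)], ("y",))).value for g in (g_chain, g_other)
    ]
    assert np.abs(with_mp[0] - with_mp[1]).max() > 1e-8  # connectivity matters

    cfg0 = ModelConfig(hidden=8, rounds=0, seed=0)
    model0 = HeteroMPNN(cfg0, {"atom": 4, "bond": 2, "global": 3})
    no_mp = [
        model0.forward(GraphBatch([_rec(0, g)], ("y",))).value for g in (g_chain, g_other)
    ]
    assert np.abs(no_mp[0] - no_mp[1]).max() < 1e-12


def test_batching_matches_single_graph_forward(toy_records):
    cfg = ModelConfig(hidden=8, rounds=1, seed=0)
    model = HeteroMPNN(cfg, {"atom": 4, "bond": 2, "global": 3})
    batched = model.forward(GraphBatch(toy_records, ("y",))).value
    singles = np.vstack(
        [model.forward(GraphBatch([r], ("y",))).value for r in toy_records]
    )
    assert np.abs(batched - singles).max() < 1e-10


# -- training --------------------------------------------------------------

def test_training_deterministic(toy_records):
    cfg = ModelConfig(hidden=8, rounds=1, max_epochs=3, seed=7, batch_size=4)
    runs = [train(cfg, toy_records[:4], toy_records[4:]) for _ in range(2)]
    assert runs[0].history[0]["train_loss"] == pytest.approx(
        runs[1].history[0]["train_loss"], abs=1e-6
    )
    assert runs[0].history[-1]["val_loss"] == pytest.approx(
        runs[1].history[-1]["val_loss"], abs=1e-6
    )


def test_train_rejects_overlapping_split(toy_records):
    cfg = ModelConfig(max_epochs=1)
    with pytest.raises(ValueError):
        train(cfg, toy_records[:4], toy_records[3:])


def test_best_val_checkpoint_monotone(toy_records):
    cfg = ModelConfig(hidden=8, max_epochs=30, seed=0, batch_size=4, lr=0.01)
    tm = train(cfg, toy_records[:4], toy_records[4:])
    best_so_far = math.inf
    checkpoints = []
    for h in tm.history:
        if h["val_loss"] < best_so_far:
            best_so_far = h["val_loss"]
            checkpoints.append(best_so_far)
    assert checkpoints == sorted(checkpoints, reverse=True)
    assert tm.best_val_loss == pytest.approx(min(h["val_loss"] for h in tm.history))


def test_gnn_recovers_linear_descriptor_label(small_records):
    """QTAIM-featurized model fits a noiseless label that is linear in pooled
    descriptors to a small fraction of the label spread."""
    records, _, _ = small_records
    train_recs, val_recs, test_recs = records[:45], records[45:52], records[52:]
    cfg = ModelConfig(hidden=16, rounds=1, lr=0.01, weight_decay=0.2,
                      batch_size=512, max_epochs=1500, patience=1500, seed=0)
    tm = train(cfg, train_recs, val_recs)
    m = evaluate(tm, test_recs)["y"]
    sd = np.std([r.labels["y"] for r in records])
    assert m.mae <= 0.1 * sd


def test_permuted_labels_hit_variance_floor(small_records):
    """With shuffled labels the model cannot beat the label-variance floor by
    more than 20% on validation."""
    records, _, _ = small_records
    rng = np.random.default_rng(0)
    ys = np.array([r.labels["y"] for r in records])
    shuffled = ys[rng.permutation(len(ys))]
    import dataclasses

    permuted = [
        dataclasses.replace(r, labels={"y": float(v)})
        for r, v in zip(records, shuffled)
    ]
    cfg = ModelConfig(hidden=16, rounds=1, lr=0.01, weight_decay=0.1,
                      batch_size=512, max_epochs=300, patience=300, seed=0)
    tm = train(cfg, permuted[:45], permuted[45:])
    # losses are on z-scored labels; the floor is the val labels' own spread
    y_tr = shuffled[:45]
    y_val = (shuffled[45:] - y_tr.mean()) / y_tr.std()
    floor = float(np.mean((y_val - y_val.mean()) ** 2))
    assert tm.best_val_loss > 0.8 * floor


def test_schema_mismatch_on_predict(toy_records):
    cfg = ModelConfig(hidden=8, max_epochs=2, seed=0)
    tm = train(cfg, toy_records[:4], toy_records[4:])
    import dataclasses

    bad = dataclasses.replace(toy_records[0], schema_hash="other")
    from qtaimnet.graphs import SchemaMismatchError

    with pytest.raises(SchemaMismatchError):
        tm.predict([bad])
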