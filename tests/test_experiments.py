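import numpy as np
import pandas as pd
import pytest

from qtaimnet.experiments import (
    EmptySplitError,
    LearningCurveSpec,
    SplitSpec,
    make_split,
    nested_subsets,
    outlier_count,
    replication_report,
    run_ood_experiment,
)
from qtaimnet.gnn import ModelConfig
from qtaimnet.graphs import FeatureSchema
from qtaimnet.pipeline import featurize_complexes, records_metadata, standardize_records


def _meta(ids, charges=None, max_z=None):
    df = pd.DataFrame({"id": ids})
    if charges is not None:
        df["charge"] = charges
    if max_z is not None:
        df["max_z"] = max_z
    return df


# -- splits ------------------------------------------------------------------

def test_charge_ood_hand_partition():
    """Charges [0,0,1,-1,2,0]: train pool = the three neutrals, test = the
    +1/-1 pair, the charge-2 molecule is excluded."""
    meta = _meta(list("abcdef"), charges=[0, 0, 1, -1, 2, 0])
    spec = SplitSpec(mode="charge_ood", seed=0, val_fraction=0.34)
    split = make_split(spec, meta)
    assert sorted(split.train + split.val) == ["a", "b", "f"]
    assert sorted(split.test) == ["c", "d"]
    assert split.excluded == ["e"]
    assert len(split.val) == 1  # round(0.34 * 3)


def test_element_ood_hand_partition():
    """max_z [8, 26, 44] with threshold 36: the Ru-containing molecule tests."""
    meta = _meta(["o", "fe", "ru"], max_z=[8, 26, 44])
    spec = SplitSpec(mode="element_ood", seed=1)
    split = make_split(spec, meta)
    assert sorted(split.train + split.val) == ["fe", "o"]
    assert split.test == ["ru"]
    assert split.excluded == []


def test_random_split_fractions_and_disjointness():
    ids = [f"m{i}" for i in range(10)]
    split = make_split(SplitSpec(mode="random", seed=3), _meta(ids))
    assert split.sizes == {"train": 8, "val": 1, "test": 1, "excluded": 0}
    parts = split.train + split.val + split.test
    assert sorted(parts) == sorted(ids)  # conservation, no overlap


def test_split_conservation_all_modes():
    rng = np.random.default_rng(5)
    n = 40
    meta = _meta(
        [f"m{i}" for i in range(n)],
        charges=rng.choice([-1, 0, 1], size=n).tolist(),
        max_z=rng.choice([8, 26, 44], size=n).tolist(),
    )
    for mode in ("random", "charge_ood", "element_ood"):
        split = make_split(SplitSpec(mode=mode, seed=0), meta)
        all_ids = split.train + split.val + split.test + split.excluded
        assert sorted(all_ids) == sorted(meta["id"])
        assert len(set(all_ids)) == n


def test_charge_ood_purity():
    rng = np.random.default_rng(7)
    charges = rng.choice([-1, 0, 1], size=30).tolist()
    meta = _meta([f"m{i}" for i in range(30)], charges=charges)
    split = make_split(SplitSpec(mode="charge_ood", seed=0), meta)
    by_id = dict(zip(meta["id"], charges))
    assert all(by_id[i] == 0 for i in split.train + split.val)
    assert all(by_id[i] in (-1, 1) for i in split.test)


def test_empty_split_raises():
    meta = _meta(["a", "b"], charges=[1, 1])
    with pytest.raises(EmptySplitError):
        make_split(SplitSpec(mode="charge_ood"), meta)
    meta2 = _meta(["a"], max_z=[8])
    with pytest.raises(EmptySplitError):
        make_split(SplitSpec(mode="element_ood"), meta2)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        make_split(SplitSpec(mode="random"), _meta(["a", "a"]))


def test_invalid_mode_rejected():
    with pytest.raises(ValueError):
        SplitSpec(mode="temporal")


# -- learning-curve machinery -------------------------------------------------

def test_nested_subsets_nest():
    pool = [f"m{i}" for i in range(120)]
    subsets = nested_subsets(pool, [50, 100], seed=4)
    assert subsets[50] == subsets[100][:50]
    assert len(set(subsets[100])) == 100


def test_nested_subsets_seeded():
    pool = [f"m{i}" for i in range(30)]
    assert nested_subsets(pool, [10], seed=2) == nested_subsets(pool, [10], seed=2)
    assert nested_subsets(pool, [10], seed=2) != nested_subsets(pool, [10], seed=3)


def test_learning_curve_spec_requires_sorted_sizes():
    with pytest.raises(ValueError):
        LearningCurveSpec(sizes=(100, 50))


# -- outlier diagnostics -------------------------------------------------------

def test_outlier_count_hand_example():
    """|Errors| [1,2,1,3,100]: median 2, MAD 1, so only 100 > 5*MAD."""
    y = np.zeros(5)
    yhat = np.array([1.0, 2.0, -1.0, 3.0, 100.0])
    assert outlier_count(y, yhat, mad_factor=5.0) == 1


def test_outlier_count_zero_mad():
    """All errors identical (MAD 0): count nonzero errors."""
    y = np.zeros(3)
    assert outlier_count(y, np.array([2.0, 2.0, 2.0])) == 3
    assert outlier_count(y, np.zeros(3)) == 0


# -- OOD experiment on the shared dataset --------------------------------------

def test_ood_experiment_two_arms(small_dataset):
    complexes, topologies, labels = small_dataset
    schema_q = FeatureSchema()
    schema_p = FeatureSchema(use_qtaim_atom=False, use_qtaim_bond=False)
    arms = {}
    for name, schema in (("qtaim", schema_q), ("plain", schema_p)):
        recs = featurize_complexes(complexes, topologies, labels, schema)
        train_ids = [r.id for r in recs]
        recs_std, _ = standardize_records(recs, train_ids, schema)
        arms[name] = recs_std
    spec = SplitSpec(mode="charge_ood", seed=0, val_fraction=0.15)
    cfg = ModelConfig(hidden=8, rounds=1, max_epochs=20, batch_size=64, seed=0)
    out = run_ood_experiment(spec, arms, cfg)
    assert out["conservation"] is True
    assert set(out["arms"]) == {"qtaim", "plain"}
    for arm in out["arms"].values():
        assert "MAE" in arm["metrics"]["y"]
        assert arm["outliers"]["y"] >= 0
    # identical split across arms: metadata-driven partition is arm-independent
    meta = records_metadata(arms["qtaim"])
    split = make_split(spec, meta)
    assert out["split"] == split.sizes


# -- replication report --------------------------------------------------------

def test_replication_report_tiny_tables(tmp_path):
    pd.DataFrame({"id": ["a", "b", "c", "d"], "charge": [0, 0, 1, -1]}).to_csv(
        tmp_path / "labels.csv", index=False
    )
    pd.DataFrame({"id": ["a", "b", "c"], "n_bond_paths": [4, 6, 5]}).to_csv(
        tmp_path / "bond_counts_low.csv", index=False
    )
    pd.DataFrame({"id": ["a", "b", "c"], "n_bond_paths": [4, 9, 6]}).to_csv(
        tmp_path / "bond_counts_high.csv", index=False
    )
    out = replication_report(tmp_path, tiers=("low", "high"), k=2)
    # diffs 0, 3, 1 -> 2 of 3 within 2
    assert out["pairs"]["low_vs_high"]["percent_within"] == pytest.approx(200.0 / 3.0)
    assert out["pairs"]["low_vs_high"]["n"] == 3
    assert out["charge_ood"] == {"train_size": 2, "test_size": 2}


def test_replication_report_missing_table(tmp_path):
    with pytest.raises(FileNotFoundError, match="bond_counts_low"):
        replication_report(tmp_path, tiers=("low",))
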