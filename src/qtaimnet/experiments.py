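"""Experiment protocols: dataset splits, learning curves, OOD comparisons.

Split modes mirror the generalizability protocol for molecular property
models:

* ``random`` — seeded shuffle into train/val/test fractions;
* ``charge_ood`` — train on a restricted charge set (default: neutral only),
  test on held-out charges (default {-1, +1}); other charges are excluded
  entirely;
* ``element_ood`` — train only on molecules whose every atom has Z at or
  below a threshold (default 36, i.e. nothing beyond Kr); test on molecules
  containing at least one atom above it.

Learning curves use nested training subsets (each smaller set is a prefix of
the larger one for the same seed) against a fixed test set.  OOD experiments
train two arms — QTAIM-featurized vs. plain one-hot — on identical ids and
report per-arm metrics plus extreme-outlier counts (|error| > 5 MAD,
configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gnn import ModelConfig, TrainedModel, evaluate, train
from .graphs import GraphRecord
from .lot import bond_count_stats

SPLIT_MODES = ("random", "charge_ood", "element_ood")


class EmptySplitError(ValueError):
    pass


@dataclass
class SplitSpec:
    mode: str = "random"
    seed: int = 0
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    train_charge: frozenset = frozenset({0})
    test_charge: frozenset = frozenset({-1, 1})
    z_threshold: int = 36
    val_fraction: float = 0.1  # carved from train in OOD modes

    def __post_init__(self) -> None:
        if self.mode not in SPLIT_MODES:
            raise ValueError(f"mode must be one of {SPLIT_MODES}")
        self.train_charge = frozenset(self.train_charge)
        self.test_charge = frozenset(self.test_charge)


@dataclass
class Split:
    train: list[str]
    val: list[str]
    test: list[str]
    excluded: list[str] = field(default_factory=list)

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "train": len(self.train), "val": len(self.val),
            "test": len(self.test), "excluded": len(self.excluded),
        }


def _carve_val(ids: list[str], fraction: float, rng) -> tuple[list[str], list[str]]:
    ids = list(ids)
    order = rng.permutation(len(ids))
    n_val = max(1, int(round(fraction * len(ids)))) if len(ids) > 1 else 0
    val = [ids[i] for i in order[:n_val]]
    train = [ids[i] for i in order[n_val:]]
    return train, val


def make_split(spec: SplitSpec, metadata: pd.DataFrame) -> Split:
    """Partition a dataset (metadata columns: id, charge, max_z).

    The produced id sets are disjoint and, with the excluded set, conserve
    the dataset size exactly.
    """
    for col in ("id",):
        if col not in metadata.columns:
            raise ValueError(f"metadata must carry column {col!r}")
    ids = metadata["id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in metadata")
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "random":
        f_train, f_val, f_test = spec.fractions
        order = rng.permutation(len(ids))
        n_train = int(round(f_train * len(ids)))
        n_val = int(round(f_val * len(ids)))
        train = [ids[i] for i in order[:n_train]]
        val = [ids[i] for i in order[n_train : n_train + n_val]]
        test = [ids[i] for i in order[n_train + n_val :]]
        return Split(train=train, val=val, test=test)

    if spec.mode == "charge_ood":
        charge = metadata.set_index("id")["charge"]
        pool = [i for i in ids if charge[i] in spec.train_charge]
        test = [i for i in ids if charge[i] in spec.test_charge]
        excluded = [i for i in ids if i not in set(pool) | set(test)]
    else:  # element_ood
        max_z = metadata.set_index("id")["max_z"]
        pool = [i for i in ids if max_z[i] <= spec.z_threshold]
        test = [i for i in ids if max_z[i] > spec.z_threshold]
        excluded = []
    if not pool:
        raise EmptySplitError(f"{spec.mode}: training pool empty after filtering")
    if not test:
        raise EmptySplitError(f"{spec.mode}: test set empty after filtering")
    train, val = _carve_val(pool, spec.val_fraction, rng)
    return Split(train=train, val=val, test=test, excluded=excluded)


# ---------------------------------------------------------------------------
# Learning curves
# ---------------------------------------------------------------------------

@dataclass
class LearningCurveSpec:
    sizes: tuple[int, ...] = (50, 100, 200, 500)
    seeds: tuple[int, ...] = (0, 1, 2)
    test_ids: tuple[str, ...] = ()
    val_fraction: float = 0.15

    def __post_init__(self) -> None:
        if tuple(sorted(self.sizes)) != tuple(self.sizes):
            raise ValueError("sizes must be sorted ascending")


def nested_subsets(pool: list[str], sizes, seed: int) -> dict[int, list[str]]:
    """Seeded shuffle; each size takes a prefix, so smaller sets nest in larger."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    shuffled = [pool[i] for i in order]
    return {size: shuffled[:size] for size in sizes}


def run_learning_curve(
    spec: LearningCurveSpec,
    records_by_arm: dict[str, list[GraphRecord]],
    config: ModelConfig,
) -> pd.DataFrame:
    """size x arm x seed grid of test metrics with nested training subsets."""
    rows = []
    for arm, records in records_by_arm.items():
        by_id = {r.id: r for r in records}
        test = [by_id[i] for i in spec.test_ids]
        pool = [r.id for r in records if r.id not in set(spec.test_ids)]
        n_val = max(1, int(round(spec.val_fraction * len(pool))))
        if max(spec.sizes) + n_val > len(pool):
            raise ValueError(
                f"largest size {max(spec.sizes)} (+{n_val} val) exceeds pool of {len(pool)}"
            )
        for seed in spec.seeds:
            subsets = nested_subsets(pool, [max(spec.sizes) + n_val], seed)
            shuffled = subsets[max(spec.sizes) + n_val]
            val_ids = shuffled[-n_val:]
            train_order = shuffled[:-n_val]
            cfg = ModelConfig(**{**config.__dict__, "seed": seed})
            for size in spec.sizes:
                train_ids = train_order[:size]
                trained = train(cfg, [by_id[i] for i in train_ids],
                                [by_id[i] for i in val_ids])
                metrics = evaluate(trained, test)
                for target, m in metrics.items():
                    rows.append({
                        "arm": arm, "seed": seed, "size": size, "target": target,
                        **m.to_dict(),
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# OOD experiments
# ---------------------------------------------------------------------------

def outlier_count(y_true, y_pred, mad_factor: float = 5.0) -> int:
    """Number of predictions with |error| > mad_factor * MAD(errors)."""
    err = np.abs(np.asarray(y_pred, dtype=float) - np.asarray(y_true, dtype=float))
    mad = float(np.median(np.abs(err - np.median(err))))
    if mad == 0.0:
        return int(np.sum(err > 0))
    return int(np.sum(err > mad_factor * mad))


def run_ood_experiment(
    spec: SplitSpec,
    records_by_arm: dict[str, list[GraphRecord]],
    config: ModelConfig,
    mad_factor: float = 5.0,
) -> dict:
    """Train every arm on the identical split; report metrics + outlier counts."""
    arms = {}
    split = None
    for arm, records in records_by_arm.items():
        meta = pd.DataFrame([{"id": r.id, **r.meta} for r in records])
        arm_split = make_split(spec, meta)
        if split is None:
            split = arm_split
        elif arm_split.sizes != split.sizes or set(arm_split.test) != set(split.test):
            raise ValueError("arms must share the identical split")
        by_id = {r.id: r for r in records}
        trained = train(config, [by_id[i] for i in split.train],
                        [by_id[i] for i in split.val])
        test = [by_id[i] for i in split.test]
        metrics = evaluate(trained, test)
        pred = trained.predict(test)
        outliers = {}
        for ti, t in enumerate(config.targets):
            y = np.array([r.labels[t] for r in test])
            outliers[t] = outlier_count(y, pred[:, ti], mad_factor)
        arms[arm] = {
            "metrics": {t: m.to_dict() for t, m in metrics.items()},
            "outliers": outliers,
        }
    n_total = len(next(iter(records_by_arm.values())))
    return {
        "split": split.sizes,
        "conservation": sum(split.sizes.values()) == n_total,
        "arms": arms,
    }


# ---------------------------------------------------------------------------
# Full-scale replication against the deposited tier tables
# ---------------------------------------------------------------------------

def replication_report(data_dir, tiers=("low", "mid", "high"), k: int = 2) -> dict:
    """Dataset statistics recomputed from deposited tier tables.

    Expects under ``data_dir``: ``labels.csv`` with columns (id, charge) and
    one ``bond_counts_<tier>.csv`` per tier with columns (id, n_bond_paths).
    Returns the pairwise percentage of molecules whose bond-path counts agree
    within ``k``, and the charge-OOD train/test sizes (train: charge 0;
    test: charge in {-1, +1}).
    """
    data_dir = Path(data_dir)
    counts = {}
    for tier in tiers:
        f = data_dir / f"bond_counts_{tier}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing tier table {f}")
        df = pd.read_csv(f)
        counts[tier] = dict(zip(df["id"], df["n_bond_paths"]))
    out = {"pairs": {}}
    for i, ta in enumerate(tiers):
        for tb in tiers[i + 1 :]:
            stats = bond_count_stats(counts[ta], counts[tb], ks=(k,))
            out["pairs"][f"{ta}_vs_{tb}"] = {
                "percent_within": stats["percent_within"][k],
                "n": stats["n"],
            }
    labels = pd.read_csv(data_dir / "labels.csv")
    out["charge_ood"] = {
        "train_size": int((labels["charge"] == 0).sum()),
        "test_size": int(labels["charge"].isin([-1, 1]).sum()),
    }
    return out
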