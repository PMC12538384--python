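"""End-to-end conveniences: complexes -> topologies -> graph records."""

from __future__ import annotations

import pandas as pd

from .graphs import (
    FeatureSchema,
    GraphRecord,
    StandardizationStats,
    build_heterograph,
    standardize_apply,
    standardize_fit,
)
from .synthetic import SyntheticComplex
from .topology import MolecularTopology


def featurize_complexes(
    complexes: list[SyntheticComplex],
    topologies: dict[str, MolecularTopology],
    labels: pd.DataFrame,
    schema: FeatureSchema,
) -> list[GraphRecord]:
    """Graph records with labels and split metadata (charge, max Z)."""
    label_map = labels.set_index("id")["y"].to_dict() if "y" in labels else {}
    records = []
    for cx in complexes:
        graph = build_heterograph(topologies[cx.id], cx, schema)
        records.append(
            GraphRecord(
                id=cx.id,
                graph=graph,
                labels={"y": float(label_map[cx.id])} if label_map else {},
                schema_hash=schema.schema_hash,
                meta={
                    "charge": cx.charge,
                    "spin": cx.spin,
                    "max_z": cx.max_z,
                    "n_atoms": cx.n_atoms,
                },
            )
        )
    return records


def standardize_records(
    records: list[GraphRecord], train_ids: list[str], schema: FeatureSchema
) -> tuple[list[GraphRecord], StandardizationStats]:
    """Fit z-scoring on the training records only, apply to all records."""
    train_set = set(train_ids)
    stats = standardize_fit([r for r in records if r.id in train_set], schema)
    return [standardize_apply(r, stats) for r in records], stats


def records_metadata(records: list[GraphRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"id": r.id, **r.meta} for r in records])
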