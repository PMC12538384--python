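"""Heterograph construction, feature standardization, on-disk record store.

A molecule becomes a heterogeneous graph with three node types:

* ``atom`` — one node per nucleus,
* ``bond`` — one node per successfully traced bond path,
* ``global`` — exactly one node carrying molecule-level state.

Typed edges connect each bond node to its two endpoint atoms (both
directions) and every atom/bond node to the global node (both directions), so
the graph is always a single connected component through the global node even
when bond paths fail — connectivity never depends on a heuristic.

Feature layout is fixed by a :class:`FeatureSchema` whose hash travels with
every dataset; standardization statistics are fit on training records only.
Undefined descriptors are NaN in stored records and are imputed to 0 after
standardization with an appended indicator column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .descriptors import DESCRIPTOR_NAMES, attach_descriptors
from .topology import MolecularTopology

NODE_TYPES = ("atom", "bond", "global")

_DEFAULT_VOCAB = ("C", "N", "O", "F", "S", "Cl", "Fe", "Co", "Ni", "Cu", "Zn",
                  "Ru", "Rh", "Pd", "Ag")


def _atomic_weight(element: str) -> float:
    from rdkit import Chem

    return Chem.GetPeriodicTable().GetAtomicWeight(element)


@dataclass(frozen=True)
class FeatureSchema:
    element_vocab: tuple[str, ...] = _DEFAULT_VOCAB
    use_qtaim_atom: bool = True
    use_qtaim_bond: bool = True

    @property
    def atom_features(self) -> tuple[str, ...]:
        names = [f"element_{el}" for el in self.element_vocab] + ["Z"]
        if self.use_qtaim_atom:
            names += [f"ncp_{d}" for d in DESCRIPTOR_NAMES]
        return tuple(names)

    @property
    def bond_features(self) -> tuple[str, ...]:
        names = ["arc_length"]
        if self.use_qtaim_bond:
            names += [f"bcp_{d}" for d in DESCRIPTOR_NAMES]
        return tuple(names)

    @property
    def global_features(self) -> tuple[str, ...]:
        return ("charge", "spin", "n_atoms", "mol_weight")

    def feature_names(self, node_type: str) -> tuple[str, ...]:
        return {
            "atom": self.atom_features,
            "bond": self.bond_features,
            "global": self.global_features,
        }[node_type]

    @property
    def schema_hash(self) -> str:
        payload = json.dumps(
            {
                "vocab": list(self.element_vocab),
                "qtaim_atom": self.use_qtaim_atom,
                "qtaim_bond": self.use_qtaim_bond,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "element_vocab": list(self.element_vocab),
            "use_qtaim_atom": self.use_qtaim_atom,
            "use_qtaim_bond": self.use_qtaim_bond,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            element_vocab=tuple(d["element_vocab"]),
            use_qtaim_atom=d["use_qtaim_atom"],
            use_qtaim_bond=d["use_qtaim_bond"],
        )


@dataclass
class HeteroGraph:
    features: dict[str, np.ndarray]  # node type -> (n_nodes, n_features)
    bond_endpoints: np.ndarray  # (n_bond, 2) sorted atom indices

    @property
    def n_atoms(self) -> int:
        return self.features["atom"].shape[0]

    @property
    def n_bonds(self) -> int:
        return self.features["bond"].shape[0]

    def edge_counts(self) -> dict[str, int]:
        na, nb = self.n_atoms, self.n_bonds
        return {
            "atom->bond": 2 * nb,
            "bond->atom": 2 * nb,
            "atom->global": na,
            "global->atom": na,
            "bond->global": nb,
            "global->bond": nb,
        }


@dataclass
class GraphRecord:
    id: str
    graph: HeteroGraph
    labels: dict[str, float] = field(default_factory=dict)
    schema_hash: str = ""
    meta: dict = field(default_factory=dict)


class SchemaMismatchError(ValueError):
    pass


class MissingRecordError(KeyError):
    pass


def build_heterograph(
    topology: MolecularTopology,
    molecule,
    schema: FeatureSchema,
) -> HeteroGraph:
    """Featurized heterograph from a topology.

    ``molecule`` supplies molecule-level metadata: any object with ``charge``
    and ``spin`` attributes (e.g. a SyntheticComplex) or a plain dict.
    Atom nodes follow input order; bond nodes are sorted by endpoint pair;
    duplicate endpoint pairs are merged keeping the higher-density bond CP.
    """
    charge = molecule["charge"] if isinstance(molecule, dict) else molecule.charge
    spin = molecule["spin"] if isinstance(molecule, dict) else molecule.spin

    desc = attach_descriptors(topology)
    nuclear = {rec["key"][0]: rec for rec in desc["nuclear"]}

    atoms = topology.atoms
    vocab = {el: i for i, el in enumerate(schema.element_vocab)}
    atom_rows = []
    for a in atoms:
        onehot = np.zeros(len(schema.element_vocab))
        if a.element in vocab:
            onehot[vocab[a.element]] = 1.0
        row = list(onehot) + [float(a.atomic_number)]
        if schema.use_qtaim_atom:
            rec = nuclear[a.index]
            row += [rec[d] for d in DESCRIPTOR_NAMES]
        atom_rows.append(row)

    by_pair: dict[tuple[int, int], dict] = {}
    for rec in desc["bond"]:
        pair = tuple(rec["key"])
        if pair in by_pair:
            warnings.warn(f"duplicate bond endpoint pair {pair}; keeping higher rho")
            if rec["rho"] <= by_pair[pair]["rho"]:
                continue
        by_pair[pair] = rec
    pairs = sorted(by_pair)
    bond_rows = []
    for pair in pairs:
        rec = by_pair[pair]
        row = [rec["arc_length"]]
        if schema.use_qtaim_bond:
            row += [rec[d] for d in DESCRIPTOR_NAMES]
        bond_rows.append(row)

    mol_weight = sum(_atomic_weight(a.element) for a in atoms)
    global_row = [[float(charge), float(spin), float(len(atoms)), mol_weight]]

    return HeteroGraph(
        features={
            "atom": np.asarray(atom_rows, dtype=float),
            "bond": np.asarray(bond_rows, dtype=float).reshape(
                len(bond_rows), len(schema.bond_features)
            ),
            "global": np.asarray(global_row, dtype=float),
        },
        bond_endpoints=np.asarray(pairs, dtype=int).reshape(len(pairs), 2),
    )


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationStats:
    """Per-node-type z-scoring statistics, fit on training records only.

    ``kept`` holds the retained column indices (zero-variance columns are
    dropped), ``nan_columns`` the kept-column positions that showed NaN in
    training and therefore get an appended indicator column.
    """

    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    kept: dict[str, list[int]]
    dropped: dict[str, list[str]]
    nan_columns: dict[str, list[int]]
    schema_hash: str

    def to_dict(self) -> dict:
        return {
            "mean": {k: list(v) for k, v in self.mean.items()},
            "std": {k: list(v) for k, v in self.std.items()},
            "kept": self.kept,
            "dropped": self.dropped,
            "nan_columns": self.nan_columns,
            "schema_hash": self.schema_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationStats":
        return cls(
            mean={k: np.asarray(v) for k, v in d["mean"].items()},
            std={k: np.asarray(v) for k, v in d["std"].items()},
            kept={k: list(v) for k, v in d["kept"].items()},
            dropped={k: list(v) for k, v in d["dropped"].items()},
            nan_columns={k: list(v) for k, v in d["nan_columns"].items()},
            schema_hash=d["schema_hash"],
        )


def standardize_fit(
    records: list[GraphRecord], schema: FeatureSchema, variance_floor: float = 1e-12
) -> StandardizationStats:
    """Population mean/sd per feature column over all nodes of the given
    (training) records; zero-variance columns are dropped and recorded."""
    if len(records) < 2:
        raise ValueError("standardization requires at least 2 training records")
    mean, std, kept, dropped, nan_cols = {}, {}, {}, {}, {}
    for nt in NODE_TYPES:
        stacked = np.vstack([r.graph.features[nt] for r in records])
        names = schema.feature_names(nt)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mu = np.nanmean(stacked, axis=0)
            sd = np.nanstd(stacked, axis=0)
        mu = np.where(np.isfinite(mu), mu, 0.0)
        sd = np.where(np.isfinite(sd), sd, 0.0)
        keep = [i for i in range(stacked.shape[1]) if sd[i] > variance_floor]
        kept[nt] = keep
        dropped[nt] = [names[i] for i in range(stacked.shape[1]) if i not in keep]
        mean[nt] = mu[keep]
        std[nt] = sd[keep]
        nan_cols[nt] = [
            j for j, i in enumerate(keep) if np.isnan(stacked[:, i]).any()
        ]
    return StandardizationStats(
        mean=mean, std=std, kept=kept, dropped=dropped, nan_columns=nan_cols,
        schema_hash=schema.schema_hash,
    )


def standardize_apply(record: GraphRecord, stats: StandardizationStats) -> GraphRecord:
    """Z-score a record; NaNs are imputed to 0 post-scaling, with one indicator
    column appended per NaN-capable feature."""
    if record.schema_hash and record.schema_hash != stats.schema_hash:
        raise SchemaMismatchError(
            f"record schema {record.schema_hash} != stats schema {stats.schema_hash}"
        )
    feats = {}
    for nt in NODE_TYPES:
        x = record.graph.features[nt][:, stats.kept[nt]]
        z = (x - stats.mean[nt]) / stats.std[nt]
        indicators = np.isnan(z[:, stats.nan_columns[nt]]).astype(float)
        z = np.nan_to_num(z, nan=0.0)
        feats[nt] = np.concatenate([z, indicators], axis=1)
    graph = HeteroGraph(features=feats, bond_endpoints=record.graph.bond_endpoints)
    return dataclasses.replace(record, graph=graph)


def standardize_invert(record: GraphRecord, stats: StandardizationStats) -> GraphRecord:
    """Inverse transform of the kept (non-indicator) columns."""
    feats = {}
    for nt in NODE_TYPES:
        n_kept = len(stats.kept[nt])
        z = record.graph.features[nt][:, :n_kept]
        feats[nt] = z * stats.std[nt] + stats.mean[nt]
    graph = HeteroGraph(features=feats, bond_endpoints=record.graph.bond_endpoints)
    return dataclasses.replace(record, graph=graph)


# ---------------------------------------------------------------------------
# On-disk store: directory of JSON records + manifest
# ---------------------------------------------------------------------------

def write_store(
    records: list[GraphRecord],
    path,
    schema: FeatureSchema,
    stats: StandardizationStats | None = None,
) -> None:
    path = Path(path)
    (path / "records").mkdir(parents=True, exist_ok=True)
    ids = []
    for rec in records:
        ids.append(rec.id)
        payload = {
            "id": rec.id,
            "schema_hash": rec.schema_hash or schema.schema_hash,
            "labels": rec.labels,
            "meta": rec.meta,
            "features": {
                nt: [[_json_float(v) for v in row] for row in rec.graph.features[nt]]
                for nt in NODE_TYPES
            },
            "feature_dims": {nt: rec.graph.features[nt].shape[1] for nt in NODE_TYPES},
            "bond_endpoints": rec.graph.bond_endpoints.tolist(),
        }
        (path / "records" / f"{rec.id}.json").write_text(json.dumps(payload))
    manifest = {
        "count": len(records),
        "ids": ids,
        "schema": schema.to_dict(),
        "schema_hash": schema.schema_hash,
        "standardization": stats.to_dict() if stats else None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _json_float(v):
    v = float(v)
    return None if not np.isfinite(v) else v


def read_manifest(path) -> dict:
    return json.loads((Path(path) / "manifest.json").read_text())


def read_store(path, ids: list[str] | None = None) -> list[GraphRecord]:
    path = Path(path)
    manifest = read_manifest(path)
    ids = manifest["ids"] if ids is None else ids
    records = []
    for mol_id in ids:
        f = path / "records" / f"{mol_id}.json"
        if not f.exists():
            raise MissingRecordError(f"record {mol_id!r} not found in store {path}")
        payload = json.loads(f.read_text())
        feats = {
            nt: np.asarray(
                [[np.nan if v is None else v for v in row] for row in payload["features"][nt]],
                dtype=float,
            ).reshape(len(payload["features"][nt]), payload["feature_dims"][nt])
            for nt in NODE_TYPES
        }
        graph = HeteroGraph(
            features=feats,
            bond_endpoints=np.asarray(payload["bond_endpoints"], dtype=int).reshape(-1, 2),
        )
        records.append(
            GraphRecord(
                id=payload["id"],
                graph=graph,
                labels=payload["labels"],
                schema_hash=payload["schema_hash"],
                meta=payload.get("meta", {}),
            )
        )
    return records
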