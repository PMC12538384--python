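import numpy as np
import pytest

from qtaimnet.graphs import (
    FeatureSchema,
    GraphRecord,
    MissingRecordError,
    SchemaMismatchError,
    build_heterograph,
    read_manifest,
    read_store,
    standardize_apply,
    standardize_fit,
    standardize_invert,
    write_store,
)
from qtaimnet.synthetic import generate_complex
from qtaimnet.topology import build_topology

from conftest import simple_atom


class Meta:
    def __init__(self, charge=0, spin=1):
        self.charge, self.spin = charge, spin


def test_diatomic_heterograph_counts(diatomic):
    topo = build_topology(diatomic)
    g = build_heterograph(topo, Meta(), FeatureSchema())
    assert (g.n_atoms, g.n_bonds) == (2, 1)
    assert g.features["global"].shape[0] == 1
    assert g.edge_counts() == {
        "atom->bond": 2, "bond->atom": 2,
        "atom->global": 2, "global->atom": 2,
        "bond->global": 1, "global->bond": 1,
    }
    assert g.bond_endpoints.tolist() == [[0, 1]]


def test_qtaim_off_bond_dimension(diatomic):
    topo = build_topology(diatomic)
    schema = FeatureSchema(use_qtaim_bond=False)
    g = build_heterograph(topo, Meta(), schema)
    assert g.features["bond"].shape[1] == 1  # arc length only
    assert schema.bond_features == ("arc_length",)


def test_schema_hash_changes_with_flags():
    assert FeatureSchema().schema_hash != FeatureSchema(use_qtaim_bond=False).schema_hash


def test_atom_permutation_gives_isomorphic_graph():
    """Relabeling atoms permutes rows but preserves the feature multisets and
    the endpoint structure."""
    cx = generate_complex(seed=21, n_ligands=4)
    atoms = cx.atoms
    perm = [2, 0, 4, 1, 3]
    permuted = [
        simple_atom(i, atoms[p].position, element=atoms[p].element)
        for i, p in enumerate(perm)
    ]
    # rebuild with identical shells so densities match exactly
    for new, old_idx in zip(permuted, perm):
        new.shells = atoms[old_idx].shells
    schema = FeatureSchema()
    g_a = build_heterograph(build_topology(atoms), cx, schema)
    g_b = build_heterograph(build_topology(permuted), cx, schema)
    assert g_a.n_atoms == g_b.n_atoms and g_a.n_bonds == g_b.n_bonds

    def sorted_rows(x):
        return np.asarray(sorted(map(tuple, x)))

    for nt in ("atom", "bond"):
        a, b = sorted_rows(g_a.features[nt]), sorted_rows(g_b.features[nt])
        assert np.allclose(np.nan_to_num(a), np.nan_to_num(b), atol=1e-6)
    mapped = sorted(tuple(sorted((perm[i], perm[j]))) for i, j in g_b.bond_endpoints)
    assert mapped == sorted(tuple(p) for p in g_a.bond_endpoints)


def _record(i, atom_rows, bond_rows, global_row, endpoints=()):
    from qtaimnet.graphs import HeteroGraph

    g = HeteroGraph(
        features={
            "atom": np.asarray(atom_rows, float),
            "bond": np.asarray(bond_rows, float).reshape(len(bond_rows), -1)
            if bond_rows else np.zeros((0, 1)),
            "global": np.asarray([global_row], float),
        },
        bond_endpoints=np.asarray(endpoints, int).reshape(len(endpoints), 2),
    )
    return GraphRecord(id=f"r{i}", graph=g, labels={"y": float(i)}, schema_hash="h")


def test_standardize_population_sd():
    """Column {1,3} -> {-1,+1} under population standard deviation."""
    recs = [
        _record(0, [[1.0, 5.0]], [[2.0]], [0.0], [(0, 0)]),
        _record(1, [[3.0, 5.0]], [[4.0]], [1.0], [(0, 0)]),
    ]

    class TinySchema:
        schema_hash = "h"

        def feature_names(self, nt):
            return {"atom": ("a0", "a1"), "bond": ("b0",), "global": ("g0",)}[nt]

    stats = standardize_fit(recs, TinySchema())
    assert stats.dropped["atom"] == ["a1"]  # constant column dropped + listed
    out = standardize_apply(recs[0], stats)
    assert out.graph.features["atom"].tolist() == [[-1.0]]
    out1 = standardize_apply(recs[1], stats)
    assert out1.graph.features["atom"].tolist() == [[1.0]]


def test_standardize_roundtrip(small_records):
    records_std, stats, schema = small_records
    rec = records_std[0]
    recovered = standardize_invert(rec, stats)
    # re-standardize and compare to the kept (non-indicator) columns
    back = standardize_apply(
        GraphRecord(id=rec.id, graph=_pad_to_schema(recovered, stats, schema),
                    labels=rec.labels, schema_hash=stats.schema_hash),
        stats,
    )
    for nt in ("atom", "bond", "global"):
        n_kept = len(stats.kept[nt])
        a = rec.graph.features[nt][:, :n_kept]
        b = back.graph.features[nt][:, :n_kept]
        assert np.abs(np.nan_to_num(a - b)).max() < 1e-10


def _pad_to_schema(record, stats, schema):
    """Rebuild full-width feature matrices with the dropped columns zeroed."""
    from qtaimnet.graphs import HeteroGraph

    feats = {}
    for nt in ("atom", "bond", "global"):
        full_width = len(schema.feature_names(nt))
        n_rows = record.graph.features[nt].shape[0]
        full = np.zeros((n_rows, full_width))
        full[:, stats.kept[nt]] = record.graph.features[nt]
        feats[nt] = full
    return HeteroGraph(features=feats, bond_endpoints=record.graph.bond_endpoints)


def test_schema_mismatch_raises(small_records):
    records_std, stats, _ = small_records
    rec = records_std[0]
    bad = GraphRecord(id=rec.id, graph=rec.graph, labels=rec.labels,
                      schema_hash="different")
    with pytest.raises(SchemaMismatchError):
        standardize_apply(bad, stats)


def test_store_roundtrip(tmp_path, small_records):
    records_std, stats, schema = small_records
    subset = records_std[:10]
    write_store(subset, tmp_path / "store", schema, stats)
    manifest = read_manifest(tmp_path / "store")
    assert manifest["count"] == 10
    assert manifest["schema_hash"] == schema.schema_hash
    back = read_store(tmp_path / "store")
    assert [r.id for r in back] == [r.id for r in subset]
    for a, b in zip(subset, back):
        for nt in ("atom", "bond", "global"):
            fa, fb = a.graph.features[nt], b.graph.features[nt]
            assert fa.shape == fb.shape
            both = np.isnan(fa) == np.isnan(fb)
            assert both.all()
            assert np.abs(np.nan_to_num(fa - fb)).max() < 1e-12
        assert a.labels == b.labels
        assert (a.graph.bond_endpoints == b.graph.bond_endpoints).all()


def test_store_missing_id(tmp_path, small_records):
    records_std, stats, schema = small_records
    write_store(records_std[:3], tmp_path / "store", schema, stats)
    with pytest.raises(MissingRecordError, match="nope"):
        read_store(tmp_path / "store", ["nope"])


def test_no_nan_after_standardization(small_records):
    """Sentinels are imputed: standardized features contain no NaN."""
    records_std, _, _ = small_records
    for rec in records_std:
        for nt in ("atom", "bond", "global"):
            assert np.isfinite(rec.graph.features[nt]).all()
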