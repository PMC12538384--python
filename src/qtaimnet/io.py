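"""File I/O: XYZ geometries, critical-point JSON records, descriptor tables.

XYZ files follow the plain convention (atom count, comment, ``El x y z`` in
angstrom); the comment line may carry ``charge=Q spin=S id=NAME`` key-value
pairs, which is how molecular metadata travels alongside geometries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .density import ANGSTROM_PER_BOHR, AtomSite
from .descriptors import DESCRIPTOR_NAMES, attach_descriptors
from .topology import MolecularTopology


def parse_xyz_comment(comment: str) -> dict:
    """Extract key=value tokens (charge, spin, id, ...) from an XYZ comment."""
    meta: dict = {}
    for token in comment.split():
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        if key in ("charge", "spin"):
            meta[key] = int(value)
        else:
            meta[key] = value
    return meta


def read_xyz(path) -> tuple[list[AtomSite], dict]:
    """Read one molecule; returns (atoms, metadata). Positions in the file are
    angstrom; the returned AtomSites are in bohr."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    n = int(lines[0].split()[0])
    meta = parse_xyz_comment(lines[1] if len(lines) > 1 else "")
    atoms = []
    for i, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {line!r}")
        atoms.append(
            AtomSite.from_angstrom(i, parts[0], [float(p) for p in parts[1:4]])
        )
    if len(atoms) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(atoms)}")
    return atoms, meta


def write_xyz(path, atoms: list[AtomSite], meta: dict | None = None) -> None:
    meta = meta or {}
    comment = " ".join(f"{k}={v}" for k, v in meta.items())
    lines = [str(len(atoms)), comment]
    for a in atoms:
        x, y, z = a.position * ANGSTROM_PER_BOHR
        lines.append(f"{a.element:<3s} {x: .10f} {y: .10f} {z: .10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def topology_record(topology: MolecularTopology, mol_id: str) -> dict:
    """JSON-serializable record of a molecule's topology and CP descriptors."""
    desc = attach_descriptors(topology)

    def cp_entry(cp, descriptors=None):
        entry = {
            "position_bohr": [float(v) for v in cp.position],
            "type": cp.cp_type,
            "signature": cp.signature,
            "eigenvalues": [float(v) for v in cp.hessian_eigenvalues],
            "rho": float(cp.rho),
            "gradient_norm": float(cp.gradient_norm),
            "owning_atoms": list(cp.owning_atoms),
        }
        if descriptors is not None:
            entry["descriptors"] = {
                k: (None if not np.isfinite(v) else float(v))
                for k, v in descriptors.items()
                if k in DESCRIPTOR_NAMES
            }
        return entry

    cps = []
    for cp, rec in zip(topology.nuclear_cps, desc["nuclear"]):
        cps.append(cp_entry(cp, rec))
    bond_descriptors = {tuple(r["key"]): r for r in desc["bond"]}
    for cp in topology.bond_cps:
        rec = bond_descriptors.get(tuple(cp.owning_atoms))
        cps.append(cp_entry(cp, rec))
    for cp in topology.ring_cps + topology.cage_cps:
        cps.append(cp_entry(cp))

    return {
        "id": mol_id,
        "atoms": [
            {
                "index": a.index,
                "element": a.element,
                "Z": a.atomic_number,
                "position_bohr": [float(v) for v in a.position],
            }
            for a in topology.atoms
        ],
        "cps": cps,
        "bond_paths": [
            {"endpoints": list(p.endpoints), "arc_length": float(p.arc_length)}
            for p in topology.bond_paths
        ],
        "counts": list(topology.counts),
        "ph_invariant": topology.poincare_hopf,
        "failed_paths": topology.failed_paths,
    }


def write_topology_json(path, topology: MolecularTopology, mol_id: str) -> None:
    Path(path).write_text(json.dumps(topology_record(topology, mol_id), indent=1))


def descriptor_table(topologies: dict[str, MolecularTopology]) -> pd.DataFrame:
    """Flatten CP descriptors to one row per CP: id, cp_kind, key, columns.

    ``key`` is the atom index for nuclear CPs and ``"i-j"`` (sorted endpoint
    pair) for bond CPs; it is the join key for level-of-theory comparison.
    """
    rows = []
    for mol_id, topo in topologies.items():
        desc = attach_descriptors(topo)
        for rec in desc["nuclear"]:
            row = {"id": mol_id, "cp_kind": "nuclear", "key": str(rec["key"][0])}
            row.update({k: rec[k] for k in DESCRIPTOR_NAMES})
            rows.append(row)
        for rec in desc["bond"]:
            i, j = rec["key"]
            row = {"id": mol_id, "cp_kind": "bond", "key": f"{i}-{j}"}
            row.update({k: rec[k] for k in DESCRIPTOR_NAMES})
            row["arc_length"] = rec["arc_length"]
            rows.append(row)
    return pd.DataFrame(rows)


def bond_path_counts(topologies: dict[str, MolecularTopology]) -> pd.Series:
    """Total traced bond paths per molecule id."""
    return pd.Series(
        {mol_id: len(t.bond_paths) for mol_id, t in topologies.items()}, name="n_bond_paths"
    )
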