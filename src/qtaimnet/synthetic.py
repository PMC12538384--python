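"""Synthetic transition-metal-complex generator.

Produces toy single-metal-center complexes with promolecular densities, paired
density "tiers" that emulate two levels of theory (a controlled shell-exponent
perturbation plus optional geometry jitter), and labels that are known linear
functions of pooled QTAIM descriptors plus Gaussian noise.  Because the label
mechanism is known exactly, every downstream stage — featurization, training,
out-of-domain splits, level-of-theory statistics — can be tested for parameter
recovery without any external data.

All randomness flows from a single root seed through a counter-based
``numpy.random.SeedSequence`` scheme, so each stage (geometry, tiers, labels)
is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import AtomSite
from .descriptors import DESCRIPTOR_NAMES, attach_descriptors
from .topology import MolecularTopology, TopologyConfig, build_topology

METAL_ELEMENTS = ("Fe", "Co", "Ni", "Cu", "Zn", "Ru", "Rh", "Pd", "Ag")
LIGAND_ELEMENTS = ("C", "N", "O", "F", "S", "Cl")

#: Ligand shell radius around the metal, bohr.
LIGAND_RADIUS = (3.5, 5.5)
#: Minimum accepted interatomic separation, bohr.
MIN_SEPARATION = 2.2

_STAGE_GEOMETRY = 0
_STAGE_TIER = 1
_STAGE_LABELS = 2


def _rng(root_seed: int, stage: int, item: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(root_seed), stage, item)))


def _id_counter(mol_id: str) -> int:
    return zlib.crc32(mol_id.encode())


class PlacementError(RuntimeError):
    """Rejection sampling failed to place a ligand."""


@dataclass
class SyntheticComplex:
    id: str
    atoms: list[AtomSite]
    charge: int
    spin: int
    tier: str = "high"  # {"low", "high"}

    @property
    def max_z(self) -> int:
        return max(a.atomic_number for a in self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def generate_complex(
    seed: int,
    n_ligands: int,
    charge: int = 0,
    metal: str | None = None,
    mol_id: str | None = None,
    max_rejections: int = 1000,
) -> SyntheticComplex:
    """One complex: metal at the origin, ligands rejection-sampled on a shell
    of 3.5-5.5 bohr with pairwise separation >= 2.2 bohr."""
    if n_ligands < 1:
        raise ValueError("n_ligands must be >= 1")
    rng = _rng(seed, _STAGE_GEOMETRY)
    if metal is None:
        metal = METAL_ELEMENTS[int(rng.integers(len(METAL_ELEMENTS)))]
    spin = int(rng.integers(1, 4))
    positions = [np.zeros(3)]
    elements = [metal]
    rejections = 0
    while len(positions) < n_ligands + 1:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(*LIGAND_RADIUS)
        candidate = radius * direction
        if min(np.linalg.norm(candidate - p) for p in positions) < MIN_SEPARATION:
            rejections += 1
            if rejections > max_rejections:
                raise PlacementError(
                    f"could not place ligand {len(positions)} after {max_rejections} rejections"
                )
            continue
        positions.append(candidate)
        elements.append(LIGAND_ELEMENTS[int(rng.integers(len(LIGAND_ELEMENTS)))])
    atoms = [
        AtomSite(index=i, element=el, position=pos)
        for i, (el, pos) in enumerate(zip(elements, positions))
    ]
    return SyntheticComplex(
        id=mol_id or f"synt-{seed:08d}",
        atoms=atoms,
        charge=int(charge),
        spin=spin,
    )


def generate_dataset(
    n: int,
    seed: int,
    charges: tuple[int, ...] = (0, 0, 1, -1),
    n_ligands_range: tuple[int, int] = (3, 8),
    metals: tuple[str, ...] = METAL_ELEMENTS,
) -> list[SyntheticComplex]:
    """A dataset of ``n`` complexes with exact round-robin charge and metal
    marginals (divisible counts give the requested proportions exactly)."""
    rng = _rng(seed, _STAGE_GEOMETRY, item=2**20)
    lo, hi = n_ligands_range
    out = []
    for i in range(n):
        n_lig = int(rng.integers(lo, hi + 1))
        out.append(
            generate_complex(
                seed=seed * 1_000_003 + i,
                n_ligands=n_lig,
                charge=charges[i % len(charges)],
                metal=metals[i % len(metals)],
                mol_id=f"synt-{seed:06d}-{i:05d}",
            )
        )
    return out


def generate_tier_pair(
    complex_: SyntheticComplex,
    eps_zeta: float,
    eps_geo: float = 0.0,
    seed: int = 0,
) -> tuple[SyntheticComplex, SyntheticComplex]:
    """(low, high) tier pair sharing the same id.

    ``high`` is the unperturbed parent.  ``low`` multiplies every shell
    exponent by (1 + u), u ~ Uniform(-eps_zeta, eps_zeta), and jitters each
    position by N(0, eps_geo^2) per coordinate — the two independent axes
    (density level of theory, geometry level of theory) of the tier contrast.
    """
    if not 0.0 <= eps_zeta <= 0.3:
        raise ValueError("eps_zeta must lie in [0, 0.3]")
    rng = _rng(seed, _STAGE_TIER, item=_id_counter(complex_.id))
    high = dataclasses.replace(complex_, tier="high")
    low_atoms = []
    for a in complex_.atoms:
        shells = tuple(
            (c, z * (1.0 + rng.uniform(-eps_zeta, eps_zeta))) for c, z in a.shells
        )
        pos = a.position + (rng.normal(size=3) * eps_geo if eps_geo > 0 else 0.0)
        low_atoms.append(
            AtomSite(index=a.index, element=a.element, position=pos, shells=shells)
        )
    low = dataclasses.replace(complex_, atoms=low_atoms, tier="low")
    return low, high


def build_topologies(
    complexes: list[SyntheticComplex], config: TopologyConfig | None = None
) -> dict[str, MolecularTopology]:
    return {cx.id: build_topology(cx.atoms, config) for cx in complexes}


def pooled_descriptors(topology: MolecularTopology) -> dict[str, float]:
    """Mean descriptor over bond CPs and over nuclear CPs, keyed
    ``"bond:<name>"`` / ``"nuclear:<name>"``.  NaN sentinels are ignored in
    the mean; an empty or all-NaN pool contributes 0."""
    desc = attach_descriptors(topology)
    out = {}
    for kind in ("bond", "nuclear"):
        records = desc[kind]
        for name in DESCRIPTOR_NAMES:
            values = np.array([r[name] for r in records], dtype=float)
            values = values[np.isfinite(values)]
            out[f"{kind}:{name}"] = float(values.mean()) if values.size else 0.0
    return out


@dataclass
class LabelRule:
    """Ground-truth label mechanism: y = sum_f w_f * pool_f
    + charge_coefficient * charge + N(0, noise_sd^2)."""

    weights: dict[str, float] = field(default_factory=dict)  # "bond:rho" -> w
    charge_coefficient: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for key in self.weights:
            kind, _, name = key.partition(":")
            if kind not in ("bond", "nuclear") or name not in DESCRIPTOR_NAMES:
                raise KeyError(f"unknown descriptor pool {key!r}")


def default_label_rule(noise_sd: float = 0.0) -> LabelRule:
    """Default synthetic label mechanism.

    Dominated by bond-CP ellipticity — a quantity that vanishes for an
    isolated atom pair and is created purely by the surrounding ligand field,
    so it cannot be read off pair distances or element identities — plus a
    density term and a charge term.  Weights put each term on a comparable
    scale given the generator's descriptor distributions.
    """
    return LabelRule(
        weights={"bond:ellipticity": 3.0, "bond:rho": 1.0, "nuclear:rho": 0.3},
        charge_coefficient=1.0,
        noise_sd=noise_sd,
    )


def assign_labels(
    complexes: list[SyntheticComplex],
    topologies: dict[str, MolecularTopology],
    rule: LabelRule,
    seed: int = 0,
) -> pd.DataFrame:
    """Label table (id, charge, spin, y) from the rule; deterministic in seed."""
    rng = _rng(seed, _STAGE_LABELS)
    rows = []
    for cx in complexes:
        if cx.id not in topologies:
            raise KeyError(f"no topology computed for complex {cx.id!r}")
        pools = pooled_descriptors(topologies[cx.id])
        y = sum(w * pools[k] for k, w in rule.weights.items())
        y += rule.charge_coefficient * cx.charge
        if rule.noise_sd > 0:
            y += rng.normal(0.0, rule.noise_sd)
        rows.append({"id": cx.id, "charge": cx.charge, "spin": cx.spin, "y": y})
    return pd.DataFrame(rows)
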