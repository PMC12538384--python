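"""Critical-point topology of a model electron density.

A critical point (CP) is a zero of the density gradient, classified by the
signature of the Hessian there: (3,-3) nuclear maxima, (3,-1) bond saddles,
(3,+1) ring saddles, (3,+3) cage minima.  Steepest-ascent trajectories
launched from each bond CP along the positive-curvature eigenvector terminate
at two nuclei and define the bond path, i.e. the atom-pair connectivity used
downstream for graph construction.  The Poincare-Hopf relation
n - b + r - c = 1 over the CP counts of an isolated molecule is used as the
extraction consistency check.

Search strategy: nuclear CPs are placed at the nuclei directly (the
promolecular density has a cusp maximum there, so Newton iteration is
ill-posed); all other CPs are found by Newton-Raphson on the gradient from a
geometric seed set (pair midpoints, triangle and tetrahedron centroids of
atoms within a cutoff), then deduplicated and classified.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import (
    BOHR_PER_ANGSTROM,
    AtomSite,
    DegenerateEvaluationError,
    ModelDensity,
)

CP_NUCLEAR = "nuclear"
CP_BOND = "bond"
CP_RING = "ring"
CP_CAGE = "cage"

_SIGNATURE_TO_TYPE = {-3: CP_NUCLEAR, -1: CP_BOND, 1: CP_RING, 3: CP_CAGE}


class TopologyError(RuntimeError):
    """Fatal failure of topology extraction (e.g. no nuclear CPs)."""


class DegenerateCPError(ValueError):
    """A Hessian eigenvalue is below the rank tolerance."""


@dataclass
class TopologyConfig:
    """Tolerances and search settings, all in atomic units unless noted."""

    grad_tol: float = 1e-10
    dedup_radius: float = 1e-3  # bohr
    rank_tol: float = 1e-10
    nucleus_capture_radius: float = 0.1  # bohr
    ascent_step: float = 0.01  # bohr
    max_steps: int = 10_000
    seed_cutoff_angstrom: float = 5.0  # pair/triangle/tetra seed cutoff
    newton_max_iter: int = 80
    newton_max_step: float = 0.5  # bohr, per-iteration step cap
    near_nucleus_reject: float = 0.3  # bohr; Newton results this close are spurious
    bbox_margin: float = 6.0  # bohr around the atoms
    path_offset: float = 1e-2  # bohr, launch offset off the bond CP
    soften_radius: float = 0.05  # bohr, cusp softening for nuclear curvature


@dataclass
class CriticalPoint:
    position: np.ndarray  # (3,) bohr
    cp_type: str
    rank: int
    signature: int
    hessian_eigenvalues: np.ndarray  # (3,) ascending, a.u.
    hessian_eigenvectors: np.ndarray  # (3,3) columns match eigenvalues
    rho: float
    gradient_norm: float
    owning_atoms: tuple[int, ...] = ()


@dataclass
class BondPath:
    bond_cp: CriticalPoint
    endpoints: tuple[int, int]  # sorted atom indices
    polyline: np.ndarray  # (N, 3) bohr, nucleus to nucleus
    arc_length: float  # bohr


@dataclass
class MolecularTopology:
    atoms: list[AtomSite]
    model: ModelDensity
    nuclear_cps: list[CriticalPoint]
    bond_cps: list[CriticalPoint]
    bond_paths: list[BondPath]
    ring_cps: list[CriticalPoint]
    cage_cps: list[CriticalPoint]
    failed_paths: int = 0
    config: TopologyConfig = field(default_factory=TopologyConfig)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            len(self.nuclear_cps),
            len(self.bond_cps),
            len(self.ring_cps),
            len(self.cage_cps),
        )

    @property
    def poincare_hopf(self) -> int:
        n, b, r, c = self.counts
        return n - b + r - c


def classify_cp(hessian_eigenvalues, rank_tol: float = 1e-10) -> str:
    """Map sorted Hessian eigenvalues to a CP type via the signature.

    Raises :class:`DegenerateCPError` when any eigenvalue magnitude falls
    below ``rank_tol`` (rank-deficient Hessian, classification undefined).
    """
    lam = np.asarray(hessian_eigenvalues, dtype=float)
    if np.any(np.abs(lam) <= rank_tol):
        raise DegenerateCPError(f"rank-deficient Hessian, eigenvalues {lam}")
    signature = int(np.sign(lam).sum())
    return _SIGNATURE_TO_TYPE[signature]


def _seed_points(model: ModelDensity, config: TopologyConfig) -> np.ndarray:
    pos = model.positions
    n = len(pos)
    cutoff = config.seed_cutoff_angstrom * BOHR_PER_ANGSTROM
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    seeds = []
    for i, j in itertools.combinations(range(n), 2):
        if dist[i, j] <= cutoff:
            seeds.append(0.5 * (pos[i] + pos[j]))
    for tri in itertools.combinations(range(n), 3):
        pairs = itertools.combinations(tri, 2)
        if all(dist[i, j] <= cutoff for i, j in pairs):
            seeds.append(pos[list(tri)].mean(axis=0))
    for quad in itertools.combinations(range(n), 4):
        pairs = itertools.combinations(quad, 2)
        if all(dist[i, j] <= cutoff for i, j in pairs):
            seeds.append(pos[list(quad)].mean(axis=0))
    if not seeds:
        return np.empty((0, 3))
    return np.asarray(seeds)


def _newton(model: ModelDensity, seed: np.ndarray, config: TopologyConfig):
    """Newton-Raphson on the density gradient; returns the converged point or None."""
    x = np.array(seed, dtype=float)
    for _ in range(config.newton_max_iter):
        try:
            _, grad, hess = model.evaluate(x)
        except DegenerateEvaluationError:
            return None
        gnorm = np.linalg.norm(grad)
        if gnorm <= config.grad_tol:
            return x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = grad  # fall back to a gradient step near singular Hessians
        norm = np.linalg.norm(step)
        if not np.isfinite(norm) or norm == 0.0:
            return None
        if norm > config.newton_max_step:
            step *= config.newton_max_step / norm
        x = x - step
    return None


def _nuclear_cp(model: ModelDensity, atom: AtomSite, config: TopologyConfig) -> CriticalPoint:
    # Cusp-softened curvature: the promolecular exponential has no finite
    # Hessian at its own nucleus, so the site curvature is evaluated with
    # d -> sqrt(d^2 + a^2).  rho keeps its exact cusp value (sum of own
    # coefficients plus the tails of the other atoms); the gradient at a
    # non-smooth maximum is taken as zero by convention.
    rho_soft, _, hess = model.evaluate(atom.position, soften=config.soften_radius)
    diff = atom.position - model._centers
    d = np.linalg.norm(diff, axis=1)
    rho = float(np.sum(model._coeff * np.exp(-model._zeta * d)))
    lam, vec = np.linalg.eigh(hess)
    return CriticalPoint(
        position=atom.position.copy(),
        cp_type=CP_NUCLEAR,
        rank=3,
        signature=-3,
        hessian_eigenvalues=lam,
        hessian_eigenvectors=vec,
        rho=rho,
        gradient_norm=0.0,
        owning_atoms=(atom.index,),
    )


def find_critical_points(
    model: ModelDensity, config: TopologyConfig | None = None
) -> list[CriticalPoint]:
    """Locate and classify all rank-3 critical points of the model density."""
    config = config or TopologyConfig()
    pos = model.positions
    lo = pos.min(axis=0) - config.bbox_margin
    hi = pos.max(axis=0) + config.bbox_margin

    cps = [_nuclear_cp(model, a, config) for a in model.atoms]

    candidates = []
    for seed in _seed_points(model, config):
        x = _newton(model, seed, config)
        if x is None:
            continue  # non-convergent seed: skipped, not fatal
        if np.any(x < lo) or np.any(x > hi):
            continue
        if np.min(np.linalg.norm(pos - x, axis=1)) < config.near_nucleus_reject:
            continue
        candidates.append(x)

    # Deduplicate: greedy merge within dedup_radius, keeping the smaller |grad|.
    scored = []
    for x in candidates:
        rho, grad, hess = model.evaluate(x)
        scored.append((np.linalg.norm(grad), x, rho, hess))
    scored.sort(key=lambda t: t[0])
    kept: list[np.ndarray] = []
    for gnorm, x, rho, hess in scored:
        if any(np.linalg.norm(x - y) < config.dedup_radius for y in kept):
            continue
        lam, vec = np.linalg.eigh(hess)
        try:
            cp_type = classify_cp(lam, config.rank_tol)
        except DegenerateCPError:
            warnings.warn(f"degenerate CP at {x} excluded (eigenvalues {lam})")
            continue
        if cp_type == CP_NUCLEAR:
            # Non-nuclear attractor: not expected for promolecular sums of
            # decaying exponentials; excluded rather than mis-counted.
            warnings.warn(f"non-nuclear density maximum at {x} excluded")
            continue
        kept.append(x)
        cps.append(
            CriticalPoint(
                position=x,
                cp_type=cp_type,
                rank=3,
                signature=int(np.sign(lam).sum()),
                hessian_eigenvalues=lam,
                hessian_eigenvectors=vec,
                rho=rho,
                gradient_norm=gnorm,
            )
        )
    return cps


class PathFailure(RuntimeError):
    """Steepest-ascent path exceeded max_steps or left the bounding box."""


def _ascend(model, start, config, lo, hi):
    """Steepest ascent until capture by a nucleus; returns (points, atom_index)."""
    pos = model.positions
    x = np.array(start, dtype=float)
    points = [x.copy()]
    h = config.ascent_step
    rho, grad, _ = model.evaluate(x)
    for _ in range(config.max_steps):
        d = np.linalg.norm(pos - x, axis=1)
        nearest = int(np.argmin(d))
        if d[nearest] <= config.nucleus_capture_radius:
            points.append(pos[nearest].copy())
            return np.asarray(points), nearest
        gnorm = np.linalg.norm(grad)
        if gnorm == 0.0:
            raise PathFailure("zero gradient on ascent path")
        step = h * grad / gnorm
        x_new = x + step
        if np.any(x_new < lo) or np.any(x_new > hi):
            raise PathFailure("ascent path left the bounding box")
        try:
            rho_new, grad_new, _ = model.evaluate(x_new)
        except DegenerateEvaluationError:
            # stepped (numerically) onto a nucleus: capture it
            nearest = int(np.argmin(np.linalg.norm(pos - x_new, axis=1)))
            points.append(pos[nearest].copy())
            return np.asarray(points), nearest
        if rho_new < rho and h > 1e-5:
            h *= 0.5  # adaptive halving keeps the path monotone in density
            continue
        x, rho, grad = x_new, rho_new, grad_new
        points.append(x.copy())
        h = config.ascent_step
    raise PathFailure("ascent exceeded max_steps")


def trace_bond_path(
    model: ModelDensity, bond_cp: CriticalPoint, config: TopologyConfig | None = None
) -> BondPath:
    """Trace the two steepest-ascent halves of a bond path to their nuclei."""
    config = config or TopologyConfig()
    if bond_cp.signature != -1:
        raise ValueError("bond path tracing requires a (3,-1) critical point")
    pos = model.positions
    lo = pos.min(axis=0) - config.bbox_margin
    hi = pos.max(axis=0) + config.bbox_margin
    v3 = bond_cp.hessian_eigenvectors[:, 2]  # positive-curvature direction
    halves = []
    atoms = []
    for sign in (+1.0, -1.0):
        start = bond_cp.position + sign * config.path_offset * v3
        points, atom = _ascend(model, start, config, lo, hi)
        halves.append(points)
        atoms.append(atom)
    if atoms[0] == atoms[1]:
        raise PathFailure("both path halves captured the same nucleus")
    # Assemble nucleus -> bond CP -> nucleus.
    poly = np.vstack([halves[0][::-1], bond_cp.position[None, :], halves[1]])
    arc = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
    endpoints = tuple(sorted(atoms))
    return BondPath(bond_cp=bond_cp, endpoints=endpoints, polyline=poly, arc_length=arc)


def build_topology(
    molecule: list[AtomSite] | ModelDensity, config: TopologyConfig | None = None
) -> MolecularTopology:
    """Full topology extraction: CP search, bond-path tracing, PH check."""
    config = config or TopologyConfig()
    model = molecule if isinstance(molecule, ModelDensity) else ModelDensity(list(molecule))
    cps = find_critical_points(model, config)
    nuclear = [cp for cp in cps if cp.cp_type == CP_NUCLEAR]
    if not nuclear:
        raise TopologyError("no nuclear critical points found")
    bonds = [cp for cp in cps if cp.cp_type == CP_BOND]
    rings = [cp for cp in cps if cp.cp_type == CP_RING]
    cages = [cp for cp in cps if cp.cp_type == CP_CAGE]
    paths: list[BondPath] = []
    failed = 0
    for cp in bonds:
        try:
            path = trace_bond_path(model, cp, config)
        except PathFailure as exc:
            failed += 1
            warnings.warn(f"bond path failed: {exc}")
            continue
        cp.owning_atoms = path.endpoints
        paths.append(path)
    topo = MolecularTopology(
        atoms=model.atoms,
        model=model,
        nuclear_cps=nuclear,
        bond_cps=bonds,
        bond_paths=paths,
        ring_cps=rings,
        cage_cps=cages,
        failed_paths=failed,
        config=config,
    )
    if topo.poincare_hopf != 1:
        warnings.warn(
            f"Poincare-Hopf violated: counts {topo.counts} give {topo.poincare_hopf}"
        )
    return topo
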