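"""Analytic promolecular electron densities.

The molecular density is a promolecule: a sum of spherically symmetric atomic
contributions, each a short expansion in exponentials

    rho_A(d) = sum_k c_k * exp(-zeta_k * d),   d = |r - R_A|  (bohr)

with c_k in electrons/bohr^3 and zeta_k in 1/bohr.  This family is fully
analytic (gradient and Hessian in closed form), strictly positive, decays to
zero at infinity, and reproduces the qualitative critical-point structure of
real molecular densities: nuclear maxima (as cusps), bond saddles between
atom pairs, and ring/cage saddles in polyatomic arrangements.  It stands in
for a DFT density wherever one would otherwise run a single-point calculation.

All density math is in atomic units; geometry I/O elsewhere is in angstrom
with BOHR_PER_ANGSTROM handling the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ANGSTROM_PER_BOHR = 0.52917721067
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR

#: Below this nucleus distance (bohr) an evaluation is considered degenerate.
NUCLEUS_UNDERFLOW = 1e-8


class DegenerateEvaluationError(ValueError):
    """Raised when the density is evaluated on (or numerically at) a nucleus."""


# Shell parameters (c in e/bohr^3, zeta in 1/bohr) for the elements the
# synthetic generator uses.  Heavier atoms get a larger, tighter core shell
# and an extra diffuse shell, mimicking how heavy-atom densities dominate
# near the center while still reaching out to ligands.
_SHELL_TABLE: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((0.35, 1.20),),
    "C": ((2.20, 2.20), (0.75, 0.90)),
    "N": ((2.70, 2.45), (0.85, 1.00)),
    "O": ((3.20, 2.70), (0.95, 1.10)),
    "F": ((3.70, 2.95), (1.00, 1.20)),
    "P": ((5.00, 3.20), (1.00, 0.85)),
    "S": ((5.40, 3.40), (1.05, 0.90)),
    "Cl": ((5.80, 3.60), (1.10, 0.95)),
    # 3d metals: big tight core + valence + diffuse shell.
    "Fe": ((9.00, 4.60), (1.60, 1.05), (0.30, 0.45)),
    "Co": ((9.40, 4.75), (1.65, 1.07), (0.30, 0.45)),
    "Ni": ((9.80, 4.90), (1.70, 1.09), (0.30, 0.45)),
    "Cu": ((10.20, 5.05), (1.75, 1.11), (0.30, 0.45)),
    "Zn": ((10.60, 5.20), (1.80, 1.13), (0.30, 0.45)),
    # 4d metals.
    "Ru": ((14.00, 5.80), (2.00, 1.20), (0.35, 0.40)),
    "Rh": ((14.40, 5.95), (2.05, 1.22), (0.35, 0.40)),
    "Pd": ((14.80, 6.10), (2.10, 1.24), (0.35, 0.40)),
    "Ag": ((15.20, 6.25), (2.15, 1.26), (0.35, 0.40)),
}

_ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "Cl": 17,
    "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30,
    "Ru": 44, "Rh": 45, "Pd": 46, "Ag": 47,
}


def atomic_number(element: str) -> int:
    if element in _ATOMIC_NUMBERS:
        return _ATOMIC_NUMBERS[element]
    from rdkit import Chem

    z = Chem.GetPeriodicTable().GetAtomicNumber(element)
    if z <= 0:
        raise KeyError(f"unknown element symbol {element!r}")
    return z


def default_shells(element: str) -> tuple[tuple[float, float], ...]:
    """Built-in shell parameters; a generic Z-scaled fallback covers symbols
    outside the explicit table."""
    if element in _SHELL_TABLE:
        return _SHELL_TABLE[element]
    z = atomic_number(element)
    shells = [(0.45 * z, 1.4 + 0.11 * z), (0.6 + 0.05 * z, 1.0)]
    if z > 18:
        shells.append((0.3, 0.45))
    return tuple(shells)


@dataclass
class AtomSite:
    """One atom of a promolecular model.

    position is in angstrom at the I/O boundary but stored here in bohr;
    use :meth:`from_angstrom` when building from file geometries.
    """

    index: int
    element: str
    position: np.ndarray  # (3,) bohr
    shells: tuple[tuple[float, float], ...] | None = None
    atomic_number: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index}: position must be a finite 3-vector")
        if self.shells is None:
            self.shells = default_shells(self.element)
        self.shells = tuple((float(c), float(z)) for c, z in self.shells)
        if not self.shells:
            raise ValueError(f"atom {self.index}: at least one shell required")
        for c, z in self.shells:
            if c <= 0 or z <= 0:
                raise ValueError(
                    f"atom {self.index}: shell coefficients and exponents must be positive"
                )
        if not self.atomic_number:
            self.atomic_number = atomic_number(self.element)

    @classmethod
    def from_angstrom(cls, index, element, position_ang, shells=None):
        pos = np.asarray(position_ang, dtype=float) * BOHR_PER_ANGSTROM
        return cls(index=index, element=element, position=pos, shells=shells)


@dataclass
class ModelDensity:
    """Promolecular density over a list of :class:`AtomSite`.

    Flattened per-shell arrays are cached for vectorized evaluation.
    """

    atoms: list[AtomSite]
    _centers: np.ndarray = field(init=False, repr=False)
    _coeff: np.ndarray = field(init=False, repr=False)
    _zeta: np.ndarray = field(init=False, repr=False)
    _shell_atom: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ModelDensity requires at least one atom")
        centers, coeff, zeta, owner = [], [], [], []
        for a in self.atoms:
            for c, z in a.shells:
                centers.append(a.position)
                coeff.append(c)
                zeta.append(z)
                owner.append(a.index)
        self._centers = np.asarray(centers, dtype=float)
        self._coeff = np.asarray(coeff, dtype=float)
        self._zeta = np.asarray(zeta, dtype=float)
        self._shell_atom = np.asarray(owner, dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def evaluate(self, point, soften: float = 0.0):
        """Density, gradient and Hessian at ``point`` (bohr, a.u. values).

        ``soften`` > 0 replaces every nucleus distance d by sqrt(d^2 + soften^2),
        removing the cusp; the topology module uses it to give nuclear sites a
        finite curvature.  Ordinary evaluations use soften = 0 (exact).
        """
        point = np.asarray(point, dtype=float)
        diff = point - self._centers  # (S, 3)
        d2 = np.einsum("ij,ij->i", diff, diff)
        if soften > 0.0:
            s = np.sqrt(d2 + soften * soften)
        else:
            s = np.sqrt(d2)
            if np.any(s < NUCLEUS_UNDERFLOW):
                raise DegenerateEvaluationError(
                    "density evaluation on top of a nucleus; offset the point"
                )
        f = self._coeff * np.exp(-self._zeta * s)  # (S,)
        rho = float(f.sum())
        # d rho / dr = -zeta * f * (diff / s); with softening s'(d)=d/s is
        # folded in because diff/s already equals u * d/s.
        w1 = -self._zeta * f / s  # (S,)
        grad = diff.T @ w1  # (3,)
        # Hessian of c*exp(-zeta*s(d)) with s = sqrt(d^2 + a^2):
        #   H = (zeta^2 f / s^2 + zeta f / s^3) diff diff^T  - (zeta f / s) I
        w2 = (self._zeta**2) * f / (s * s) + self._zeta * f / (s**3)
        hess = np.einsum("i,ij,ik->jk", w2, diff, diff)
        hess += np.eye(3) * w1.sum()
        hess = 0.5 * (hess + hess.T)
        return rho, grad, hess


def eval_density(model: ModelDensity, point):
    """rho (a.u.), gradient (3,) and symmetric Hessian (3,3) at ``point`` in bohr.

    Raises :class:`DegenerateEvaluationError` within 1e-8 bohr of a nucleus,
    where the promolecular cusp makes the derivatives singular.
    """
    point = np.asarray(point, dtype=float)
    if point.shape != (3,) or not np.all(np.isfinite(point)):
        raise ValueError("point must be a finite 3-vector")
    return model.evaluate(point)
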