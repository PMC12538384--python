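"""Scalar QTAIM descriptors evaluated at critical points.

Thirteen named scalars are computed from the density value and the sorted
Hessian eigenvalues (lambda1 <= lambda2 <= lambda3) at a critical point:

* rho, grad_norm
* lap_rho = lambda1 + lambda2 + lambda3 (Laplacian of the density)
* hess_det = lambda1 * lambda2 * lambda3
* lambda1, lambda2, lambda3
* ellipticity = lambda1/lambda2 - 1 (deviation from cylindrical bonding)
* eta = |lambda1| / lambda3
* G_kinetic — Abramov gradient-expansion kinetic energy density,
  G = (3/10) (3 pi^2)^(2/3) rho^(5/3) + (1/6) lap_rho,
  the standard estimate when only rho and its Laplacian are available
  (the |grad rho|^2 term vanishes at a critical point)
* V_potential = (1/4) lap_rho - 2 G (local virial relation)
* H_total = G + V
* abs_V_over_G = |V| / G (bond-character indicator)

Ratios with a vanishing denominator are recorded as NaN sentinels, never
raised; downstream featurization imputes them explicitly.

The registry is extensible: externally produced descriptor tables may carry
extra columns, which are passed through untouched.
"""

from __future__ import annotations

import math

import numpy as np

from .density import ModelDensity
from .topology import CriticalPoint, MolecularTopology

#: Canonical descriptor column order.
DESCRIPTOR_NAMES = (
    "rho",
    "grad_norm",
    "lap_rho",
    "hess_det",
    "lambda1",
    "lambda2",
    "lambda3",
    "ellipticity",
    "eta",
    "G_kinetic",
    "V_potential",
    "H_total",
    "abs_V_over_G",
)

#: Descriptors that can legitimately be undefined (NaN sentinel).
SENTINEL_CAPABLE = ("ellipticity", "eta", "abs_V_over_G")

_ABRAMOV_CF = 0.3 * (3.0 * math.pi**2) ** (2.0 / 3.0)


def abramov_kinetic(rho: float, lap_rho: float) -> float:
    """Kinetic energy density at a CP from the Abramov gradient expansion."""
    return _ABRAMOV_CF * rho ** (5.0 / 3.0) + lap_rho / 6.0


def descriptors_from_values(rho, grad_norm, eigenvalues) -> dict[str, float]:
    """Descriptor set from raw CP quantities; eigenvalues sorted ascending."""
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    l1, l2, l3 = (float(v) for v in lam)
    lap = l1 + l2 + l3
    g = abramov_kinetic(rho, lap)
    v = 0.25 * lap - 2.0 * g
    out = {
        "rho": float(rho),
        "grad_norm": float(grad_norm),
        "lap_rho": lap,
        "hess_det": l1 * l2 * l3,
        "lambda1": l1,
        "lambda2": l2,
        "lambda3": l3,
        "ellipticity": l1 / l2 - 1.0 if l2 != 0.0 else math.nan,
        "eta": abs(l1) / l3 if l3 != 0.0 else math.nan,
        "G_kinetic": g,
        "V_potential": v,
        "H_total": g + v,
        "abs_V_over_G": abs(v) / g if g != 0.0 else math.nan,
    }
    return out


def compute_descriptors(model: ModelDensity, cp: CriticalPoint) -> dict[str, float]:
    """Full descriptor set at a converged critical point."""
    return descriptors_from_values(cp.rho, cp.gradient_norm, cp.hessian_eigenvalues)


def attach_descriptors(topology: MolecularTopology) -> dict[str, list[dict]]:
    """Descriptors for every nuclear and bond CP of a topology.

    Returns ``{"nuclear": [...], "bond": [...]}`` where each entry carries the
    CP key (atom index for nuclear CPs, sorted endpoint pair for bond CPs),
    so tiers can be matched deterministically.
    """
    out: dict[str, list[dict]] = {"nuclear": [], "bond": []}
    for cp in topology.nuclear_cps:
        rec = {"key": (cp.owning_atoms[0],)}
        rec.update(compute_descriptors(topology.model, cp))
        out["nuclear"].append(rec)
    for path in topology.bond_paths:
        cp = path.bond_cp
        rec = {"key": tuple(path.endpoints), "arc_length": path.arc_length}
        rec.update(compute_descriptors(topology.model, cp))
        out["bond"].append(rec)
    return out
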