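"""Post-convergence diagnostics of excited-state solutions.

Spin contamination as the integral of the negative part of the spin
density, the spin-purified energy E_s = 2 E_m - E_t, the Le Bahers
charge-transfer distance d_CT with transferred charge q_CT, and dipole
moments.  Densities arrive as weighted point sets (site populations for
the model backend; a grid quadrature for volumetric data), so all
integrals are discrete sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DensitySample",
    "spin_contamination",
    "spin_purified_energy",
    "ct_distance",
    "dipole_moment",
]


@dataclass
class DensitySample:
    """Signed density values times integration weights at given points."""

    points: np.ndarray   # (n, 3) positions in Bohr
    weights: np.ndarray  # (n,) electrons per point (signed for differences)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.weights = np.asarray(self.weights, float)
        if not (np.all(np.isfinite(self.points)) and np.all(np.isfinite(self.weights))):
            raise ValueError("density sample contains non-finite values")
        if self.points.shape[0] != self.weights.shape[0]:
            raise ValueError("points and weights length mismatch")

    def __sub__(self, other: "DensitySample") -> "DensitySample":
        if self.points.shape != other.points.shape or \
                np.max(np.abs(self.points - other.points)) > 1e-10:
            raise ValueError("density samples on different point sets")
        return DensitySample(self.points.copy(), self.weights - other.weights)


def spin_contamination(rho_up: DensitySample, rho_dn: DensitySample) -> float:
    """c = integral of -rho_s over the region where rho_s < 0 (electrons).

    rho_s = rho_up - rho_dn; a spin-mixed open-shell singlet determinant
    with the unpaired electrons on disjoint fragments gives c ~ 1.
    """
    if np.max(np.abs(rho_up.points - rho_dn.points)) > 1e-10:
        raise ValueError("spin densities on mismatched point sets")
    rho_s = rho_up.weights - rho_dn.weights
    return float(np.sum(np.maximum(0.0, -rho_s)))


def spin_purified_energy(E_m: float, E_t: float) -> float:
    """Purified singlet energy E_s = 2 E_m - E_t from mixed and triplet runs."""
    return 2.0 * E_m - E_t


def ct_distance(delta_rho: DensitySample) -> tuple[float, float]:
    """Charge-transfer distance and transferred charge from a density change.

    q_CT is the integral of the positive part of delta_rho; d_CT is the
    Euclidean norm of the delta_rho dipole divided by q_CT.
    """
    w = delta_rho.weights
    q_ct = float(np.sum(np.maximum(0.0, w)))
    if q_ct < 1e-12:
        raise ValueError("transferred charge below 1e-12: d_CT undefined")
    dip = w @ delta_rho.points
    return float(np.linalg.norm(dip) / q_ct), q_ct


def dipole_moment(rho_total: DensitySample, core_charges: np.ndarray,
                  positions: np.ndarray) -> np.ndarray:
    """mu = sum_p z_p r_p - sum_k w_k r_k (atomic units)."""
    core = np.asarray(core_charges, float) @ np.atleast_2d(positions)
    elec = rho_total.weights @ rho_total.points
    return core - elec
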