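"""Numeric electronic Hessian, saddle-point order, and rotation scans.

The saddle-point order of a stationary SCF solution is the number of
negative eigenvalues of the electronic Hessian in the orbital-rotation
coordinates.  Here the Hessian is built by central finite differences of
the analytic gradient along each rotation pair and symmetrized; model
systems are small, so a dense symmetric eigendecomposition replaces
iterative partial solvers.  Rotation scans trace the energy along a
single orbital-rotation angle together with the local quadratic
quasi-Newton model (gradient plus diagonal-Hessian curvature), which is
the diagnostic for the variational-collapse mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .orbital_space import (KappaStep, OrbitalState, apply_unitary,
                            diagonal_hessian, electronic_gradient,
                            mo_hamiltonian, nonredundant_pairs,
                            subspace_diagonalize)
from .units import HARTREE_TO_EV

__all__ = [
    "HessianReport",
    "numeric_hessian",
    "saddle_order",
    "diagonal_order_estimate",
    "rotation_scan",
    "analyze_state",
    "RotationScanResult",
]


@dataclass
class HessianReport:
    """Eigenvalue analysis of the electronic Hessian at a state."""

    eigenvalues: np.ndarray      # ascending, in eV
    order_all: int               # negative-eigenvalue count
    order_filtered: int          # count with |lambda| above the threshold
    diagonal_estimate: int       # negative diagonal-approximation elements
    magnitude_threshold: float   # eV


@dataclass
class RotationScanResult:
    angles: np.ndarray           # radians
    energies: np.ndarray         # Ha, absolute
    model: np.ndarray            # local quadratic model energies (Ha)
    gradient: float              # dE/dtheta at 0 (Ha/rad)
    curvature: float             # diagonal-Hessian model curvature (Ha/rad^2)


def _gradient_at(state: OrbitalState, backend, pairs):
    _, F = backend.evaluate(state.C, state.f)
    return np.concatenate([
        electronic_gradient(mo_hamiltonian(state.C[sp], F[sp]),
                            state.f[sp], pairs[sp])
        for sp in range(state.n_spins)])


def _displace(state: OrbitalState, pairs, direction: int, h: float):
    vec = np.zeros(sum(len(p) for p in pairs))
    vec[direction] = h
    vals, k = [], 0
    for p in pairs:
        vals.append(vec[k:k + len(p)])
        k += len(p)
    kappa = KappaStep(pairs=pairs, values=tuple(vals))
    return apply_unitary(state, kappa).rebase()


def numeric_hessian(state: OrbitalState, backend, fd_step: float = 1e-4,
                    pairs=None) -> np.ndarray:
    """Finite-difference electronic Hessian over nonredundant pairs (Ha).

    Central differences of the analytic gradient along each rotation
    direction, symmetrized as (H + H^T)/2.  Exact to O(fd_step^2) at
    stationary points; the frame rotation introduces O(step * gradient)
    asymmetry away from stationarity, which symmetrization suppresses.
    """
    if pairs is None:
        pairs = tuple(nonredundant_pairs(fs) for fs in state.f)
    n = sum(len(p) for p in pairs)
    H = np.zeros((n, n))
    base = state.rebase()
    for a in range(n):
        gp = _gradient_at(_displace(base, pairs, a, +fd_step), backend, pairs)
        gm = _gradient_at(_displace(base, pairs, a, -fd_step), backend, pairs)
        H[a] = (gp - gm) / (2.0 * fd_step)
    return 0.5 * (H + H.T)


def saddle_order(eigs: np.ndarray, magnitude_threshold: float = 0.0) -> int:
    """Count of negative eigenvalues, optionally with |lambda| above a floor.

    Eigenvalues and threshold in the same units (eV in reports); small
    negative eigenvalues are excluded when the threshold is positive.
    """
    eigs = np.asarray(eigs, float)
    neg = eigs < 0
    if magnitude_threshold > 0:
        neg &= np.abs(eigs) > magnitude_threshold
    return int(np.count_nonzero(neg))


def diagonal_order_estimate(eps, f, pairs=None) -> int:
    """Negative-element count of the diagonal Hessian approximation.

    ``eps``/``f`` may be single-spin vectors or per-spin sequences.
    """
    if isinstance(eps, (tuple, list)):
        return sum(diagonal_order_estimate(e, fs) for e, fs in zip(eps, f))
    eps, f = np.asarray(eps, float), np.asarray(f, float)
    p = nonredundant_pairs(f) if pairs is None else pairs
    d = diagonal_hessian(eps, f, p)
    return int(np.count_nonzero(d < 0))


def analyze_state(state: OrbitalState, backend, fd_step: float = 1e-4,
                  magnitude_threshold: float = 1.0) -> HessianReport:
    """Full saddle-order analysis of a state (eigenvalues reported in eV)."""
    H = numeric_hessian(state, backend, fd_step)
    eigs = np.sort(np.linalg.eigvalsh(H)) * HARTREE_TO_EV
    _, eps = subspace_diagonalize(state, backend.evaluate(state.C, state.f)[1])
    return HessianReport(
        eigenvalues=eigs,
        order_all=saddle_order(eigs, 0.0),
        order_filtered=saddle_order(eigs, magnitude_threshold),
        diagonal_estimate=diagonal_order_estimate(eps, state.f),
        magnitude_threshold=magnitude_threshold,
    )


def rotation_scan(state: OrbitalState, backend, pair, angles,
                  spin: int = 0, eps=None) -> RotationScanResult:
    """Energy along a single orbital-rotation angle, plus the local model.

    The quadratic model E(0) + g*theta + d*theta^2/2 uses the analytic
    gradient and the diagonal Hessian element of the scanned pair,
    mirroring the quasi-Newton view of the landscape at the start point.
    By default the orbital energies entering the curvature come from
    subspace diagonalization of the state's own Fock matrix; pass ``eps``
    (per-spin vectors) to model what the optimizer sees at an initial
    guess, whose available eigenvalues are those of the preceding
    ground-state calculation.
    """
    angles = np.asarray(angles, float)
    i, j = int(pair[0]), int(pair[1])
    base = state.rebase()
    pairs = tuple(np.array([[i, j]]) if sp == spin else np.zeros((0, 2), int)
                  for sp in range(state.n_spins))
    energies = np.empty(len(angles))
    for k, th in enumerate(angles):
        kappa = KappaStep(pairs=pairs,
                          values=tuple(np.array([th]) if sp == spin else np.zeros(0)
                                       for sp in range(state.n_spins)))
        rotated = apply_unitary(base, kappa)
        energies[k] = backend.evaluate(rotated.C, rotated.f)[0]

    E0, F = backend.evaluate(base.C, base.f)
    H = mo_hamiltonian(base.C[spin], F[spin])
    f = base.f[spin]
    g = float(electronic_gradient(H, f, np.array([[i, j]]))[0])
    if eps is None:
        _, eps = subspace_diagonalize(base, F)
    d = float(diagonal_hessian(eps[spin], f, np.array([[i, j]]))[0])
    model = E0 + g * angles + 0.5 * d * angles**2
    return RotationScanResult(angles=angles, energies=energies, model=model,
                              gradient=g, curvature=d)
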