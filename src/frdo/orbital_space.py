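"""Orbital representation and the exponential-unitary parametrization.

Molecular orbitals are expanded in a fixed basis, ``psi = chi C``, and
variational orbital optimization reduces to finding an anti-Hermitian
matrix ``kappa`` such that ``C = C0 exp(kappa)`` makes the energy
stationary.  This module provides the orbital-state container, the matrix
exponential, the transformation of the Hamiltonian to the current orbital
basis, the electronic gradient over nonredundant orbital-rotation pairs,
the diagonal Hessian approximation used as quasi-Newton preconditioner,
the squared residual of the self-consistent-field equations used as the
convergence measure, and subspace diagonalization within blocks of
equally occupied orbitals.

All backends are real, so kappa is a real antisymmetric matrix and the
orbital coefficients stay real throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .units import HARTREE_TO_EV

__all__ = [
    "OrbitalState",
    "KappaStep",
    "MOHamiltonian",
    "nonredundant_pairs",
    "all_pairs",
    "kappa_matrix",
    "expm_antihermitian",
    "apply_unitary",
    "mo_hamiltonian",
    "electronic_gradient",
    "diagonal_hessian",
    "ks_residual",
    "residual_from_gradient",
    "subspace_diagonalize",
    "fix_column_signs",
]

SPIN_NAMES = ("up", "down")


@dataclass
class OrbitalState:
    """Per-spin orbital coefficients, reference orbitals and occupations.

    ``C[s]`` holds the current coefficient matrix of spin channel ``s``
    (0 = up, 1 = down), ``C0[s]`` the reference (anchor) orbitals the
    exponential transformation is applied to, and ``f[s]`` the integer
    occupation vector with entries in {0, 1}.
    """

    C0: tuple[np.ndarray, ...]
    C: tuple[np.ndarray, ...]
    f: tuple[np.ndarray, ...]
    n_valence: int

    @property
    def M(self) -> int:
        return self.C[0].shape[0]

    @property
    def n_spins(self) -> int:
        return len(self.C)

    def rebase(self) -> "OrbitalState":
        """Re-anchor the reference orbitals at the current orbitals."""
        return replace(self, C0=tuple(c.copy() for c in self.C))

    def check_orthonormal(self, S: np.ndarray | None = None, tol: float = 1e-10) -> None:
        M = self.M
        S = np.eye(M) if S is None else S
        for c in self.C:
            dev = np.max(np.abs(c.T @ S @ c - np.eye(M)))
            if dev > tol:
                raise ValueError(f"orbitals not orthonormal (deviation {dev:.2e})")


@dataclass
class KappaStep:
    """Anti-Hermitian rotation parameters over orbital index pairs.

    ``pairs[s]`` is an (n_pairs, 2) integer array of (i, j) with i < j for
    spin channel s, and ``values[s]`` the corresponding real rotation
    parameters; kappa_ji = -kappa_ij is implied.
    """

    pairs: tuple[np.ndarray, ...]
    values: tuple[np.ndarray, ...]

    def to_matrix(self, M: int, spin: int) -> np.ndarray:
        return kappa_matrix(self.pairs[spin], self.values[spin], M)


def nonredundant_pairs(f: np.ndarray) -> np.ndarray:
    """Index pairs (i < j) with f_i != f_j: the nonredundant rotations.

    The energy is invariant under rotations within equal-occupation
    blocks, so these pairs span the full variational freedom.
    """
    idx = np.arange(len(f))
    i, j = np.meshgrid(idx, idx, indexing="ij")
    mask = (i < j) & (f[i] != f[j])
    return np.column_stack([i[mask], j[mask]])


def all_pairs(M: int) -> np.ndarray:
    """All index pairs (i < j) — the full kappa parametrization."""
    i, j = np.triu_indices(M, k=1)
    return np.column_stack([i, j])


def kappa_matrix(pairs: np.ndarray, values: np.ndarray, M: int) -> np.ndarray:
    """Assemble the full antisymmetric matrix from pair parameters."""
    K = np.zeros((M, M))
    if len(pairs):
        K[pairs[:, 0], pairs[:, 1]] = values
        K[pairs[:, 1], pairs[:, 0]] = -values
    return K


def expm_antihermitian(kappa: np.ndarray | KappaStep, M: int | None = None,
                       spin: int = 0) -> np.ndarray:
    """Unitary U = exp(kappa) for real antisymmetric kappa.

    Computed exactly through the Hermitian eigendecomposition of
    ``i kappa``; the result of a real antisymmetric input is real and is
    returned as such.
    """
    if isinstance(kappa, KappaStep):
        if M is None:
            raise ValueError("basis size M required with a KappaStep input")
        K = kappa.to_matrix(M, spin)
    else:
        K = np.asarray(kappa, dtype=float)
    if not np.all(np.isfinite(K)):
        raise ValueError("kappa contains non-finite entries")
    if K.shape[0] != K.shape[1]:
        raise ValueError("kappa must be square")
    w, V = np.linalg.eigh(1j * K)
    U = (V * np.exp(-1j * w)) @ V.conj().T
    return np.ascontiguousarray(U.real)


def apply_unitary(state: OrbitalState, kappa: KappaStep) -> OrbitalState:
    """C_sigma = C0_sigma exp(kappa_sigma); reference orbitals unchanged."""
    M = state.M
    newC = []
    for s in range(state.n_spins):
        U = expm_antihermitian(kappa.to_matrix(M, s))
        newC.append(state.C0[s] @ U)
    return replace(state, C=tuple(newC))


def mo_hamiltonian(C: np.ndarray, H_AO: np.ndarray) -> np.ndarray:
    """Hamiltonian (Fock) matrix in the current-orbital basis: C^T H C."""
    if C.shape[0] != H_AO.shape[0]:
        raise ValueError("dimension mismatch between C and H_AO")
    H = C.T @ H_AO @ C
    return 0.5 * (H + H.T)


def electronic_gradient(H_MO: np.ndarray, f: np.ndarray,
                        pairs: np.ndarray) -> np.ndarray:
    """dE/dkappa_ij = 2 (f_j - f_i) H_ij over the given pairs."""
    if len(pairs) == 0:
        return np.zeros(0)
    i, j = pairs[:, 0], pairs[:, 1]
    return 2.0 * (f[j] - f[i]) * H_MO[i, j]


def diagonal_hessian(eps: np.ndarray, f: np.ndarray,
                     pairs: np.ndarray) -> np.ndarray:
    """Diagonal Hessian approximation 2 (eps_i - eps_j)(f_j - f_i)."""
    if len(pairs) == 0:
        return np.zeros(0)
    i, j = pairs[:, 0], pairs[:, 1]
    return 2.0 * (eps[i] - eps[j]) * (f[j] - f[i])


def ks_residual(H_MO: Sequence[np.ndarray], f: Sequence[np.ndarray],
                n_valence: int) -> float:
    """Squared residual of the SCF equations, eV^2 per valence electron.

    r = (1/N) sum_sigma sum_i f_i sum_{j: f_j != f_i} |H_ji|^2, with the
    Lagrange multipliers lambda_ij identified with the Hamiltonian matrix
    within equal-occupation subspaces, so only couplings between orbitals
    of unequal occupation survive.  Converted from Hartree^2 to eV^2.
    """
    if n_valence <= 0:
        raise ValueError("n_valence must be positive")
    r = 0.0
    for H, fs in zip(H_MO, f):
        occ = fs.astype(bool)
        block = H[np.ix_(occ, ~occ)]
        r += float(np.sum(block**2))
    return r * HARTREE_TO_EV**2 / n_valence


def residual_from_gradient(g: np.ndarray, n_valence: int) -> float:
    """Equivalent residual from the pair gradient: (ev^2/4N) * ||g||^2.

    Valid for integer occupations, where (f_j - f_i)^2 = 1 on every
    active pair; used during constrained optimization where only the
    reduced gradient is available.
    """
    if n_valence <= 0:
        raise ValueError("n_valence must be positive")
    return float(np.dot(g, g)) * HARTREE_TO_EV**2 / (4.0 * n_valence)


def fix_column_signs(C: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each column positive."""
    k = np.argmax(np.abs(C), axis=0)
    signs = np.sign(C[k, np.arange(C.shape[1])])
    signs[signs == 0] = 1.0
    return C * signs


def subspace_diagonalize(state: OrbitalState,
                         H_AO: Sequence[np.ndarray],
                         freeze: Sequence[np.ndarray] | None = None
                         ) -> tuple[OrbitalState, tuple[np.ndarray, ...]]:
    """Diagonalize the Hamiltonian within equal-occupation blocks.

    Rotations within blocks of equal occupation leave the energy
    unchanged; this canonicalizes the orbitals and yields the orbital
    energies reported after convergence.  Orbitals listed in ``freeze``
    (per spin) are excluded from the rotation and keep their columns
    bit-identical; their reported energy is the diagonal expectation
    value.  Returns the rotated state (re-anchored) and per-spin
    eigenvalue vectors.
    """
    newC, all_eps = [], []
    for s in range(state.n_spins):
        C, fs = state.C[s], state.f[s]
        frozen = np.zeros(state.M, dtype=bool)
        if freeze is not None:
            frozen[np.asarray(freeze[s], dtype=int)] = True
        H = mo_hamiltonian(C, H_AO[s])
        Cnew = C.copy()
        eps = np.diag(H).copy()
        for occ_val in np.unique(fs):
            idx = np.where((fs == occ_val) & ~frozen)[0]
            if len(idx) == 0:
                continue
            block = H[np.ix_(idx, idx)]
            w, V = np.linalg.eigh(block)
            Cnew[:, idx] = fix_column_signs(C[:, idx] @ V)
            eps[idx] = w
        newC.append(Cnew)
        all_eps.append(eps)
    out = replace(state, C=tuple(newC)).rebase()
    return out, tuple(all_eps)
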