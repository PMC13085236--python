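"""Frozen-orbital constraints and the maximum overlap method (MOM).

The freeze step of freeze-and-release keeps the hole and excited-electron
orbitals fixed by excluding every pairwise rotation that touches them;
the remaining orbitals relax through a unitary transformation restricted
to the relaxed subspace.  MOM is the occupation controller of the DO-MOM
baseline: each iteration it occupies the orbitals with the largest
squared projections onto the occupied space of the initial guess.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .orbital_space import (KappaStep, OrbitalState, expm_antihermitian,
                            mo_hamiltonian)

__all__ = [
    "FrozenSet",
    "MOMReference",
    "frozen_pair_mask",
    "constrained_transform",
    "reduced_hamiltonian",
    "mom_overlaps",
    "mom_weights",
    "mom_select",
]


@dataclass
class FrozenSet:
    """Per-spin partition into relaxed (``s``) and frozen orbital indices."""

    s: tuple[np.ndarray, ...]
    frozen: tuple[np.ndarray, ...]

    def validate(self, M: int) -> None:
        for rel, fro in zip(self.s, self.frozen):
            union = np.union1d(rel, fro)
            if len(np.intersect1d(rel, fro)) or len(union) != M or \
                    union.min() != 0 or union.max() != M - 1:
                raise ValueError("relaxed/frozen sets must partition 0..M-1")


@dataclass
class MOMReference:
    """Occupied columns of the initial-guess orbitals, fixed for a run."""

    C_ref_occ: tuple[np.ndarray, ...]

    @property
    def N_occ(self) -> tuple[int, ...]:
        return tuple(c.shape[1] for c in self.C_ref_occ)


def frozen_pair_mask(excitations, M: int, n_spins: int = 2) -> FrozenSet:
    """Freeze every rotation pair touching a hole or particle orbital.

    ``excitations`` is a list of (hole_idx, particle_idx, spin) tuples.
    Only the spin channel carrying an excitation has orbitals frozen.
    """
    frozen: list[set] = [set() for _ in range(n_spins)]
    for h, p, spin in excitations:
        if not (0 <= h < M and 0 <= p < M):
            raise IndexError(f"excitation indices ({h}, {p}) out of range for M={M}")
        frozen[spin].update((h, p))
    s, fro = [], []
    for sp in range(n_spins):
        fro.append(np.array(sorted(frozen[sp]), dtype=int))
        s.append(np.setdiff1d(np.arange(M), fro[-1]))
    return FrozenSet(s=tuple(s), frozen=tuple(fro))


def constrained_transform(state: OrbitalState, kappa_reduced: KappaStep,
                          fs: FrozenSet) -> OrbitalState:
    """Apply exp(kappa) within the relaxed subspace only.

    Relaxed columns i become sum_{k in s} C0_k [exp(kappa)]_ki; frozen
    columns are copied bit-identically from the reference.
    """
    newC = []
    for sp in range(state.n_spins):
        rel = fs.s[sp]
        C = state.C0[sp].copy()
        if len(rel) > 1:
            K = kappa_reduced.to_matrix(len(rel), sp)
            C[:, rel] = state.C0[sp][:, rel] @ expm_antihermitian(K)
        newC.append(C)
    return replace(state, C=tuple(newC))


def reduced_hamiltonian(state: OrbitalState, H_AO, fs: FrozenSet,
                        spin: int) -> np.ndarray:
    """N x N Hamiltonian over the relaxed orbitals of one spin channel."""
    rel = fs.s[spin]
    return mo_hamiltonian(state.C[spin][:, rel], H_AO)


def mom_overlaps(ref: MOMReference, S: np.ndarray, C: np.ndarray,
                 spin: int) -> np.ndarray:
    """Overlap matrix Omega_ri between reference occupied and current orbitals."""
    return ref.C_ref_occ[spin].T @ S @ C


def mom_weights(omega: np.ndarray) -> np.ndarray:
    """Squared projections w_i = sum_r |Omega_ri|^2 onto the occupied space."""
    return np.sum(omega**2, axis=0)


def mom_select(w: np.ndarray, N_occ: int, f_current: np.ndarray,
               tie_tol: float = 1e-12) -> np.ndarray:
    """Occupy the N_occ orbitals of largest weight; ties keep current f.

    Weights equal to within ``tie_tol`` are ranked by the current
    occupation (occupied first), which prevents occupation oscillation
    when an orbital pair mixes symmetrically.
    """
    if N_occ == 0:
        return np.zeros_like(f_current)
    # lexicographic: primary key quantized weight, secondary current occupation
    quant = np.round(w / tie_tol) if tie_tol > 0 else w
    order = np.lexsort((-f_current, -quant))
    f = np.zeros_like(f_current)
    f[order[:N_occ]] = 1
    return f
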