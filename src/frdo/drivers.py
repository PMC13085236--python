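"""End-to-end orbital-optimization drivers.

Pipeline pieces: direct-minimization ground state, initial-guess
construction by occupation swapping, the constrained (freeze) phase, the
unconstrained (release) saddle search, the DO-MOM baseline, and the
composed freeze-and-release driver.

Each phase is a quasi-Newton loop in the exponential parametrization:
at every iteration the current orbitals become the new reference, the
gradient over nonredundant rotation pairs is evaluated from the Fock
matrix in the current-orbital basis, and convergence is measured by the
squared residual of the SCF equations in eV^2 per valence electron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constraints_mom import (FrozenSet, MOMReference, constrained_transform,
                              frozen_pair_mask, mom_overlaps, mom_select,
                              mom_weights, reduced_hamiltonian)
from .optimizers import QuasiNewtonState, lbfgs_step, lsr1_step, make_preconditioner
from .orbital_space import (KappaStep, OrbitalState, apply_unitary,
                            diagonal_hessian, electronic_gradient,
                            ks_residual, mo_hamiltonian, nonredundant_pairs,
                            all_pairs, residual_from_gradient,
                            subspace_diagonalize)
from .units import HARTREE_TO_EV

__all__ = [
    "RunSettings",
    "SolutionReport",
    "minimize_ground_state",
    "build_initial_guess",
    "build_triplet_guess",
    "run_constrained",
    "run_released",
    "run_do_mom",
    "run_frdo",
]


@dataclass
class RunSettings:
    """Optimizer thresholds and step caps.

    Residual tolerances are in eV^2 per valence electron: 4e-8 for full
    convergence, a looser 4e-3 for the constrained phase.  Step caps are
    on the max-norm of the kappa step: 0.2 for minimization phases and
    DO-MOM, 0.1 for the released saddle search.
    """

    tol_full: float = 4e-8
    tol_constrained: float = 4e-3
    max_iter: int = 333
    max_step_ground: float = 0.2
    max_step_constrained: float = 0.2
    max_step_released: float = 0.1
    max_step_domom: float = 0.2
    memory: int = 20
    precond_floor: float = 1e-3

    def __post_init__(self):
        for name in ("tol_full", "tol_constrained", "max_iter",
                     "max_step_ground", "max_step_constrained",
                     "max_step_released", "max_step_domom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tol_constrained < self.tol_full:
            raise ValueError("tol_constrained must be >= tol_full")


@dataclass
class SolutionReport:
    """Converged (or flagged) result of an optimization run."""

    energy: float
    residual: float
    converged: bool
    iterations: dict
    state: OrbitalState
    eps: tuple
    trace: list = field(default_factory=list)
    ground_energy: float | None = None
    excitation_energy_ev: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def total_iterations(self) -> int:
        return sum(v for k, v in self.iterations.items() if k != "total")


def _spin_pairs(f, mode: str):
    if mode == "nonredundant":
        return tuple(nonredundant_pairs(fs) for fs in f)
    M = len(f[0])
    return tuple(all_pairs(M) for _ in f)


def _split(vec, pairs):
    out, k = [], 0
    for p in pairs:
        out.append(vec[k:k + len(p)])
        k += len(p)
    return tuple(out)


def _full_space_loop(backend, state, pairs, stepper, precond, tol, max_step,
                     settings, mom_ref=None, phase=""):
    """Quasi-Newton loop over the full (or full-nonredundant) pair space."""
    qn = QuasiNewtonState(precond=precond, max_step=max_step, m=settings.memory)
    trace, prev_g, prev_step = [], None, None
    n_steps = 0
    converged = False
    f = tuple(np.asarray(x, float) for x in state.f)
    E = np.nan
    H_MO = None
    for it in range(settings.max_iter + 1):
        if mom_ref is not None:
            newf = []
            for sp in range(state.n_spins):
                omega = mom_overlaps(mom_ref, backend.S, state.C[sp], sp)
                w = mom_weights(omega)
                newf.append(mom_select(w, mom_ref.N_occ[sp], f[sp]))
            newf = tuple(np.asarray(x, float) for x in newf)
            if any(np.any(a != b) for a, b in zip(newf, f)):
                # occupations changed: the energy function over kappa is a
                # different one now, so stale curvature pairs are dropped
                qn.memory.clear()
                prev_g = prev_step = None
            f = newf
            state = replace(state, f=f)
        E, F = backend.evaluate(state.C, state.f)
        H_MO = [mo_hamiltonian(state.C[sp], F[sp]) for sp in range(state.n_spins)]
        g = np.concatenate([
            electronic_gradient(H_MO[sp], f[sp], pairs[sp])
            for sp in range(state.n_spins)])
        r = ks_residual(H_MO, f, backend.n_valence)
        trace.append({"phase": phase, "iteration": it, "energy": E,
                      "residual": r,
                      "max_step": float(np.max(np.abs(prev_step))) if prev_step is not None and prev_step.size else 0.0})
        if r <= tol:
            converged = True
            break
        if it == settings.max_iter:
            break
        if prev_g is not None:
            qn.push(prev_step, g - prev_g)
        step = stepper(qn, g)
        kappa = KappaStep(pairs=pairs, values=_split(step, pairs))
        state = apply_unitary(state, kappa).rebase()
        prev_g, prev_step = g, step
        n_steps += 1
    return state, E, trace, n_steps, converged, H_MO


def minimize_ground_state(backend, settings: RunSettings | None = None) -> SolutionReport:
    """Direct minimization of the aufbau ground state (L-BFGS).

    Starts from the backend's damped-SCF starting guess with aufbau
    occupations; the diagonal Hessian of the guess (positive-clamped
    inside L-BFGS) preconditions the quasi-Newton steps.
    """
    settings = settings or RunSettings()
    C, f = backend.sad_guess()
    state = OrbitalState(C0=tuple(c.copy() for c in C),
                         C=tuple(c.copy() for c in C),
                         f=tuple(f), n_valence=backend.n_valence)
    state, eps = subspace_diagonalize(state, backend.evaluate(state.C, state.f)[1])
    pairs = _spin_pairs(state.f, "nonredundant")
    precond = np.concatenate([
        make_preconditioner(diagonal_hessian(eps[sp], state.f[sp], pairs[sp]),
                            settings.precond_floor)
        for sp in range(state.n_spins)])
    state, E, trace, n, conv, H_MO = _full_space_loop(
        backend, state, pairs, lbfgs_step, precond, settings.tol_full,
        settings.max_step_ground, settings, phase="ground")
    state, eps = subspace_diagonalize(state, backend.evaluate(state.C, state.f)[1])
    return SolutionReport(energy=E, residual=trace[-1]["residual"],
                          converged=conv, iterations={"ground": n},
                          state=state, eps=eps, trace=trace)


def _validate_excitations(excitations, f):
    for h, p, sp in excitations:
        if f[sp][h] != 1:
            raise ValueError(f"hole orbital {h} (spin {sp}) is not occupied")
        if f[sp][p] != 0:
            raise ValueError(f"particle orbital {p} (spin {sp}) is not virtual")


def build_initial_guess(ground: SolutionReport, excitations,
                        backend) -> tuple[OrbitalState, MOMReference]:
    """Swap hole/particle occupations on the ground-state orbitals.

    Coefficients are kept at the ground-state orbitals; only occupation
    numbers change.  The MOM reference (occupied guess columns) is
    captured here, fixed for the whole run.
    """
    f = tuple(x.copy() for x in ground.state.f)
    _validate_excitations(excitations, f)
    for h, p, sp in excitations:
        f[sp][h], f[sp][p] = 0.0, 1.0
    guess = replace(ground.state, f=f).rebase()
    ref = MOMReference(C_ref_occ=tuple(
        guess.C[sp][:, guess.f[sp] == 1].copy() for sp in range(guess.n_spins)))
    return guess, ref


def build_triplet_guess(ground: SolutionReport, excitations,
                        backend) -> tuple[OrbitalState, MOMReference, FrozenSet]:
    """Triplet companion guess: the hole is taken in the opposite spin.

    For each (hole, particle, spin) excitation the electron is removed
    from the hole orbital of the *other* spin channel and added to the
    particle orbital of the given channel, giving an S_z = 1 determinant
    used for spin purification E_s = 2 E_m - E_t.
    """
    f = tuple(x.copy() for x in ground.state.f)
    M = ground.state.M
    frozen: list[set] = [set() for _ in f]
    for h, p, sp in excitations:
        other = 1 - sp
        if f[other][h] != 1:
            raise ValueError(f"hole orbital {h} (spin {other}) is not occupied")
        if f[sp][p] != 0:
            raise ValueError(f"particle orbital {p} (spin {sp}) is not virtual")
        f[other][h] = 0.0
        f[sp][p] = 1.0
        frozen[other].add(h)
        frozen[sp].add(p)
    guess = replace(ground.state, f=f).rebase()
    ref = MOMReference(C_ref_occ=tuple(
        guess.C[sp][:, guess.f[sp] == 1].copy() for sp in range(guess.n_spins)))
    fs = FrozenSet(
        s=tuple(np.setdiff1d(np.arange(M), sorted(fr)) for fr in frozen),
        frozen=tuple(np.array(sorted(fr), dtype=int) for fr in frozen))
    return guess, ref, fs


def run_constrained(state: OrbitalState, backend, excitations,
                    settings: RunSettings | None = None,
                    eps_guess=None, frozen: FrozenSet | None = None):
    """Freeze phase: L-BFGS minimization with hole/particle orbitals fixed.

    Optimizes only rotation pairs inside the relaxed subspace, to the
    loose constrained tolerance; frozen columns are bit-identical to the
    guess.  Afterward the Hamiltonian is diagonalized within
    equal-occupation subspaces, refreshing the orbital energies that
    precondition the release phase.

    Returns (state', eps_refreshed, trace, n_steps, converged).
    """
    settings = settings or RunSettings()
    fs = frozen if frozen is not None else frozen_pair_mask(
        excitations, state.M, state.n_spins)
    fs.validate(state.M)
    # reduced pair space: nonredundant pairs inside the relaxed subspace
    red_pairs = tuple(nonredundant_pairs(state.f[sp][fs.s[sp]])
                      for sp in range(state.n_spins))
    if eps_guess is None:
        _, eps_guess = subspace_diagonalize(
            state, backend.evaluate(state.C, state.f)[1])
    precond = np.concatenate([
        make_preconditioner(
            diagonal_hessian(eps_guess[sp][fs.s[sp]], state.f[sp][fs.s[sp]],
                             red_pairs[sp]),
            settings.precond_floor)
        for sp in range(state.n_spins)])

    qn = QuasiNewtonState(precond=precond, max_step=settings.max_step_constrained,
                          m=settings.memory)
    trace, prev_g, prev_step = [], None, None
    n_steps, converged = 0, False
    state = state.rebase()
    for it in range(settings.max_iter + 1):
        E, F = backend.evaluate(state.C, state.f)
        g_parts = []
        for sp in range(state.n_spins):
            Hred = reduced_hamiltonian(state, F[sp], fs, sp)
            g_parts.append(electronic_gradient(
                Hred, state.f[sp][fs.s[sp]], red_pairs[sp]))
        g = np.concatenate(g_parts)
        r = residual_from_gradient(g, backend.n_valence)
        trace.append({"phase": "constrained", "iteration": it, "energy": E,
                      "residual": r,
                      "max_step": float(np.max(np.abs(prev_step))) if prev_step is not None and prev_step.size else 0.0})
        if r <= settings.tol_constrained:
            converged = True
            break
        if it == settings.max_iter:
            break
        if prev_g is not None:
            qn.push(prev_step, g - prev_g)
        step = lbfgs_step(qn, g)
        kappa = KappaStep(pairs=red_pairs, values=_split(step, red_pairs))
        state = constrained_transform(state, kappa, fs).rebase()
        prev_g, prev_step = g, step
        n_steps += 1
    # canonicalize the relaxed orbitals only: frozen columns stay
    # bit-identical to the guess, their energies are expectation values
    state, eps = subspace_diagonalize(
        state, backend.evaluate(state.C, state.f)[1], freeze=fs.frozen)
    return state, eps, trace, n_steps, converged


def run_released(state: OrbitalState, backend,
                 settings: RunSettings | None = None,
                 eps_refreshed=None) -> SolutionReport:
    """Release phase: unconstrained L-SR1 saddle search over all pairs.

    The signed preconditioner from the refreshed orbital energies drives
    uphill steps along negative-curvature directions; converged when the
    residual falls below the full tolerance.
    """
    settings = settings or RunSettings()
    if eps_refreshed is None:
        state, eps_refreshed = subspace_diagonalize(
            state, backend.evaluate(state.C, state.f)[1])
    pairs = _spin_pairs(state.f, "nonredundant")
    precond = np.concatenate([
        make_preconditioner(diagonal_hessian(eps_refreshed[sp], state.f[sp],
                                             pairs[sp]),
                            settings.precond_floor)
        for sp in range(state.n_spins)])
    state, E, trace, n, conv, H_MO = _full_space_loop(
        backend, state, pairs, lsr1_step, precond, settings.tol_full,
        settings.max_step_released, settings, phase="released")
    state, eps = subspace_diagonalize(state, backend.evaluate(state.C, state.f)[1])
    return SolutionReport(energy=E, residual=trace[-1]["residual"],
                          converged=conv, iterations={"released": n},
                          state=state, eps=eps, trace=trace)


def run_do_mom(guess: OrbitalState, mom_ref: MOMReference, backend,
               settings: RunSettings | None = None,
               eps_guess=None) -> SolutionReport:
    """DO-MOM baseline: L-SR1 over the full pair space with MOM occupations.

    At each iteration the occupied orbitals are those with the largest
    squared projection onto the occupied space of the initial guess; the
    preconditioner is the diagonal Hessian of the guess, kept fixed.
    The full pair space is used because occupations may change mid-run.
    """
    settings = settings or RunSettings()
    if eps_guess is None:
        _, eps_guess = subspace_diagonalize(
            guess, backend.evaluate(guess.C, guess.f)[1])
    pairs = _spin_pairs(guess.f, "all")
    precond = np.concatenate([
        make_preconditioner(diagonal_hessian(eps_guess[sp], guess.f[sp],
                                             pairs[sp]),
                            settings.precond_floor)
        for sp in range(guess.n_spins)])
    state, E, trace, n, conv, H_MO = _full_space_loop(
        backend, guess.rebase(), pairs, lsr1_step, precond,
        settings.tol_full, settings.max_step_domom, settings,
        mom_ref=mom_ref, phase="domom")
    state, eps = subspace_diagonalize(state, backend.evaluate(state.C, state.f)[1])
    return SolutionReport(energy=E, residual=trace[-1]["residual"],
                          converged=conv, iterations={"domom": n},
                          state=state, eps=eps, trace=trace)


def _resolve_backend(spec_or_backend):
    from .model_backend import PPPDimerSpec, build_ppp
    if isinstance(spec_or_backend, PPPDimerSpec):
        return build_ppp(spec_or_backend)
    return spec_or_backend


def _resolve_excitations(excitations, backend, ground):
    from .model_backend import suggest_ct_excitation
    if isinstance(excitations, str) and excitations == "auto":
        return [suggest_ct_excitation(backend, ground.state.C, ground.state.f,
                                      eps=ground.eps)]
    return list(excitations)


def attach_diagnostics(report: SolutionReport, backend,
                       ground: SolutionReport) -> SolutionReport:
    """Charge-transfer and spin diagnostics relative to the ground state."""
    from .descriptors import ct_distance, dipole_moment, spin_contamination
    rho_ex = backend.density(report.state.C, report.state.f)
    rho_gs = backend.density(ground.state.C, ground.state.f)
    rho_up = backend.density(report.state.C, report.state.f, spin=0)
    rho_dn = backend.density(report.state.C, report.state.f, spin=1)
    diag = dict(report.diagnostics)
    try:
        d_ct, q_ct = ct_distance(rho_ex - rho_gs)
        diag["d_CT"], diag["q_CT"] = d_ct, q_ct
    except ValueError:
        diag["d_CT"], diag["q_CT"] = float("nan"), 0.0
    diag["spin_contamination"] = spin_contamination(rho_up, rho_dn)
    mu = dipole_moment(rho_ex, backend.core_charges, backend.positions)
    diag["dipole"] = [float(x) for x in mu]
    report.diagnostics = diag
    report.ground_energy = ground.energy
    report.excitation_energy_ev = (report.energy - ground.energy) * HARTREE_TO_EV
    return report


def run_frdo(spec_or_backend, excitations="auto",
             settings: RunSettings | None = None,
             ground: SolutionReport | None = None,
             triplet: bool = False) -> SolutionReport:
    """Freeze-and-release: guess -> constrained minimization -> saddle search.

    The reported iteration count is the sum of the constrained and
    released phases.  Diagnostics (d_CT, q_CT, spin contamination,
    dipole) are attached relative to the ground state.
    """
    settings = settings or RunSettings()
    backend = _resolve_backend(spec_or_backend)
    if ground is None:
        ground = minimize_ground_state(backend, settings)
    exc = _resolve_excitations(excitations, backend, ground)
    if triplet:
        guess, mom_ref, fs = build_triplet_guess(ground, exc, backend)
    else:
        guess, mom_ref = build_initial_guess(ground, exc, backend)
        fs = None
    state_c, eps_c, trace_c, n_c, conv_c = run_constrained(
        guess, backend, exc, settings, eps_guess=ground.eps, frozen=fs)
    report = run_released(state_c, backend, settings, eps_refreshed=eps_c)
    report.trace = trace_c + report.trace
    report.iterations = {"constrained": n_c,
                         "released": report.iterations["released"]}
    report.iterations["total"] = n_c + report.iterations["released"]
    report.converged = report.converged and True  # release decides convergence
    return attach_diagnostics(report, backend, ground)
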