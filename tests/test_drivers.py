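"""End-to-end optimization drivers."""

import numpy as np
import pytest

from frdo.drivers import (RunSettings, build_initial_guess,
                          minimize_ground_state,
                          run_constrained, run_do_mom, run_frdo, run_released)
from frdo.hessian_analysis import rotation_scan
from frdo.model_backend import (build_ppp, random_instance,
                                scf_fixed_point, suggest_ct_excitation)
from frdo.orbital_space import (electronic_gradient, mo_hamiltonian,
                                nonredundant_pairs)


def gradient_norm(backend, state):
    pairs = tuple(nonredundant_pairs(f) for f in state.f)
    _, F = backend.evaluate(state.C, state.f)
    g = np.concatenate([
        electronic_gradient(mo_hamiltonian(state.C[s], F[s]), state.f[s],
                            pairs[s]) for s in range(2)])
    return np.linalg.norm(g)


class TestGroundState:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scf_fixed_point(self, seed):
        backend = build_ppp(random_instance(seed, max_sites=6))
        report = minimize_ground_state(backend)
        assert report.converged
        E_scf, *_ = scf_fixed_point(backend)
        assert report.energy == pytest.approx(E_scf, abs=1e-9)

    @pytest.mark.parametrize("seed", (10, 11, 12))
    def test_gradient_small_at_exit(self, seed):
        # the residual threshold 4e-8 eV^2 per electron bounds the
        # gradient norm at sqrt(4 N tol)/Ha_to_eV ~ 4e-5 a.u.
        backend = build_ppp(random_instance(seed, max_sites=8))
        report = minimize_ground_state(backend)
        assert report.converged
        assert gradient_norm(backend, report.state) < 1e-4

    def test_already_converged_exits_immediately(self, decoupled_backend,
                                                 decoupled_ground):
        again = minimize_ground_state(decoupled_backend)
        assert again.iterations["ground"] == decoupled_ground.iterations["ground"]
        assert again.energy == pytest.approx(decoupled_ground.energy, abs=1e-14)


class TestInitialGuess:
    def test_homo_lumo_swap_changes_two_entries(self, decoupled_backend,
                                                decoupled_ground):
        exc = suggest_ct_excitation(decoupled_backend,
                                    decoupled_ground.state.C,
                                    decoupled_ground.state.f,
                                    eps=decoupled_ground.eps)
        guess, _ = build_initial_guess(decoupled_ground, [exc],
                                       decoupled_backend)
        diff = np.sum(guess.f[exc[2]] != decoupled_ground.state.f[exc[2]])
        assert diff == 2

    def test_two_excitations_change_four_entries(self, decoupled_backend,
                                                 decoupled_ground):
        f = decoupled_ground.state.f
        occ_up = np.where(f[0] == 1)[0]
        vir_up = np.where(f[0] == 0)[0]
        occ_dn = np.where(f[1] == 1)[0]
        vir_dn = np.where(f[1] == 0)[0]
        exc = [(int(occ_up[-1]), int(vir_up[0]), 0),
               (int(occ_dn[-1]), int(vir_dn[0]), 1)]
        guess, _ = build_initial_guess(decoupled_ground, exc,
                                       decoupled_backend)
        total = sum(np.sum(guess.f[s] != f[s]) for s in range(2))
        assert total == 4

    def test_guess_energy_above_ground(self, decoupled_backend,
                                       decoupled_ground):
        exc = suggest_ct_excitation(decoupled_backend,
                                    decoupled_ground.state.C,
                                    decoupled_ground.state.f,
                                    eps=decoupled_ground.eps)
        guess, _ = build_initial_guess(decoupled_ground, [exc],
                                       decoupled_backend)
        E = decoupled_backend.evaluate(guess.C, guess.f)[0]
        assert E >= decoupled_ground.energy

    def test_invalid_hole_rejected(self, decoupled_backend, decoupled_ground):
        vir = int(np.where(decoupled_ground.state.f[0] == 0)[0][0])
        with pytest.raises(ValueError):
            build_initial_guess(decoupled_ground, [(vir, vir, 0)],
                                decoupled_backend)


class TestConstrained:
    def _guess(self, backend, ground):
        exc = suggest_ct_excitation(backend, ground.state.C, ground.state.f,
                                    eps=ground.eps)
        guess, _ = build_initial_guess(ground, [exc], backend)
        return exc, guess

    def test_energy_monotonically_decreasing(self, collapse_backend):
        ground = minimize_ground_state(collapse_backend)
        exc, guess = self._guess(collapse_backend, ground)
        _, _, trace, _, conv = run_constrained(guess, collapse_backend, [exc],
                                               eps_guess=ground.eps)
        energies = [rec["energy"] for rec in trace]
        assert all(b <= a + 1e-10 for a, b in zip(energies, energies[1:]))
        assert conv

    def test_frozen_columns_unchanged(self, collapse_backend):
        ground = minimize_ground_state(collapse_backend)
        exc, guess = self._guess(collapse_backend, ground)
        state_c, *_ = run_constrained(guess, collapse_backend, [exc],
                                      eps_guess=ground.eps)
        for col in (exc[0], exc[1]):
            assert state_c.C[exc[2]][:, col].tobytes() == \
                guess.C[exc[2]][:, col].tobytes()

    def test_no_freeze_aufbau_reduces_to_ground_minimization(
            self, decoupled_backend, decoupled_ground):
        state_c, _, _, _, conv = run_constrained(
            decoupled_ground.state, decoupled_backend, [],
            eps_guess=decoupled_ground.eps)
        E = decoupled_backend.evaluate(state_c.C, state_c.f)[0]
        assert conv
        assert E == pytest.approx(decoupled_ground.energy, abs=1e-8)


class TestReleased:
    def test_stationary_start_exits_immediately(self, decoupled_backend,
                                                decoupled_ground):
        report = run_released(decoupled_ground.state, decoupled_backend)
        assert report.converged
        assert report.iterations["released"] == 0

    def test_ct_state_is_stationary_and_above_ground(self, decoupled_backend,
                                                     decoupled_ground):
        backend = decoupled_backend
        exc = suggest_ct_excitation(backend, decoupled_ground.state.C,
                                    decoupled_ground.state.f,
                                    eps=decoupled_ground.eps)
        guess, _ = build_initial_guess(decoupled_ground, [exc], backend)
        state_c, eps_c, *_ = run_constrained(guess, backend, [exc],
                                             eps_guess=decoupled_ground.eps)
        report = run_released(state_c, backend, eps_refreshed=eps_c)
        assert report.converged
        assert gradient_norm(backend, report.state) < 1e-6
        assert report.energy > decoupled_ground.energy

    def test_solution_stationary_under_rotation_scans(self, decoupled_backend,
                                                      decoupled_ground):
        backend = decoupled_backend
        report = run_frdo(backend, "auto", ground=decoupled_ground)
        rng = np.random.default_rng(0)
        pairs = nonredundant_pairs(report.state.f[0])
        h = 1e-4
        for k in rng.choice(len(pairs), size=3, replace=False):
            scan = rotation_scan(report.state, backend, pairs[k],
                                 np.array([-h, 0.0, h]), spin=0)
            dE = (scan.energies[2] - scan.energies[0]) / (2 * h)
            assert abs(dE) < 1e-5  # extremal at angle 0


class TestDOMOM:
    def test_decoupled_agrees_with_frdo(self, decoupled_backend,
                                        decoupled_ground):
        backend = decoupled_backend
        exc = suggest_ct_excitation(backend, decoupled_ground.state.C,
                                    decoupled_ground.state.f,
                                    eps=decoupled_ground.eps)
        guess, ref = build_initial_guess(decoupled_ground, [exc], backend)
        frdo = run_frdo(backend, [exc], ground=decoupled_ground)
        domom = run_do_mom(guess, ref, backend, eps_guess=decoupled_ground.eps)
        assert domom.converged and frdo.converged
        assert domom.energy == pytest.approx(frdo.energy, abs=1e-8)

    def test_occupation_count_conserved(self, collapse_backend):
        ground = minimize_ground_state(collapse_backend)
        exc = suggest_ct_excitation(collapse_backend, ground.state.C,
                                    ground.state.f, eps=ground.eps)
        guess, ref = build_initial_guess(ground, [exc], collapse_backend)
        report = run_do_mom(guess, ref, collapse_backend, eps_guess=ground.eps)
        for s in range(2):
            assert report.state.f[s].sum() == guess.f[s].sum()


class TestFRDO:
    def test_end_to_end_converges_with_positive_excitation(
            self, decoupled_spec):
        report = run_frdo(decoupled_spec)
        assert report.converged
        assert report.excitation_energy_ev > 0

    def test_iteration_accounting(self, decoupled_spec):
        report = run_frdo(decoupled_spec)
        assert report.iterations["total"] == (
            report.iterations["constrained"] + report.iterations["released"])

    def test_deterministic_traces(self, collapse_spec):
        r1 = run_frdo(collapse_spec)
        r2 = run_frdo(collapse_spec)
        assert len(r1.trace) == len(r2.trace)
        for a, b in zip(r1.trace, r2.trace):
            assert a["energy"] == b["energy"]
            assert a["residual"] == b["residual"]

    def test_never_below_domom_on_collapse_fixture(self, collapse_backend):
        """The collapse is downhill: FR-DO stays above the collapsed state."""
        ground = minimize_ground_state(collapse_backend)
        exc = suggest_ct_excitation(collapse_backend, ground.state.C,
                                    ground.state.f, eps=ground.eps)
        guess, ref = build_initial_guess(ground, [exc], collapse_backend)
        frdo = run_frdo(collapse_backend, [exc], ground=ground)
        domom = run_do_mom(guess, ref, collapse_backend, eps_guess=ground.eps)
        assert frdo.energy >= domom.energy

    def test_triplet_companion_and_spin_purification(self, decoupled_spec):
        from frdo.descriptors import spin_purified_energy
        mixed = run_frdo(decoupled_spec)
        triplet = run_frdo(decoupled_spec, triplet=True)
        assert triplet.converged
        E_s = spin_purified_energy(mixed.energy, triplet.energy)
        assert np.isfinite(E_s)


class TestRunSettings:
    def test_defaults_follow_reported_protocol(self):
        s = RunSettings()
        assert s.tol_full == pytest.approx(4e-8)
        assert s.tol_constrained == pytest.approx(4e-3)
        assert s.max_iter == 333
        assert s.max_step_constrained == pytest.approx(0.2)
        assert s.max_step_released == pytest.approx(0.1)
        assert s.max_step_domom == pytest.approx(0.2)

    def test_inconsistent_tolerances_rejected(self):
        with pytest.raises(ValueError):
            RunSettings(tol_constrained=1e-9)
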