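"""Variational collapse: DO-MOM versus freeze-and-release.

On a tuned short-separation dimer with a local-exchange mean field, the
charge-transfer guess sits next to a spurious charge-delocalized
minimum reached by mixing the hole with an occupied orbital at an angle
below 45 degrees — too small for the maximum overlap method to detect.
DO-MOM slides downhill into it; freeze-and-release first relaxes with
the hole and excited-electron orbitals frozen, then climbs to the
target saddle point.  The collapsed solution is lower in energy with a
smaller transferred charge: an artifact, not a better answer.
"""

from frdo import (build_ppp, generate_fixture, minimize_ground_state,
                  run_frdo, run_do_mom, suggest_ct_excitation)
from frdo.drivers import attach_diagnostics, build_initial_guess

spec = generate_fixture(1, "collapse")
backend = build_ppp(spec)
ground = minimize_ground_state(backend)
exc = suggest_ct_excitation(backend, ground.state.C, ground.state.f,
                            eps=ground.eps)
print(f"excitation: hole {exc[0]} -> particle {exc[1]} (spin up)")

frdo = run_frdo(backend, [exc], ground=ground)
guess, mom_ref = build_initial_guess(ground, [exc], backend)
domom = run_do_mom(guess, mom_ref, backend, eps_guess=ground.eps)
attach_diagnostics(domom, backend, ground)

for name, rep in (("freeze-and-release", frdo), ("DO-MOM", domom)):
    print(f"{name:>20s}: E = {rep.energy: .6f} Ha "
          f"({rep.excitation_energy_ev:.3f} eV), "
          f"d_CT = {rep.diagnostics['d_CT']:.3f} Bohr, "
          f"q_CT = {rep.diagnostics['q_CT']:.3f} e, "
          f"converged = {rep.converged}")
print(f"DO-MOM collapsed {frdo.energy - domom.energy:.3f} Ha below the "
      f"target charge-transfer solution")
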