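"""Saddle-point order before and after the constrained step.

Excited-state solutions are saddle points of the electronic energy; the
number of negative Hessian eigenvalues (the saddle order) decides which
directions a quasi-Newton search must climb.  At the raw ground-orbital
guess the estimate is poor; after constrained relaxation it matches the
converged solution — the reason freeze-and-release reaches the target.
"""

import numpy as np

from frdo import (build_ppp, generate_fixture, minimize_ground_state,
                  numeric_hessian, saddle_order, suggest_ct_excitation)
from frdo.drivers import build_initial_guess, run_constrained, run_released
from frdo.hessian_analysis import diagonal_order_estimate
from frdo.units import HARTREE_TO_EV

spec = generate_fixture(1, "collapse")
backend = build_ppp(spec)
ground = minimize_ground_state(backend)
exc = suggest_ct_excitation(backend, ground.state.C, ground.state.f,
                            eps=ground.eps)
guess, _ = build_initial_guess(ground, [exc], backend)

order_guess = saddle_order(np.linalg.eigvalsh(numeric_hessian(guess, backend)))
diag_guess = diagonal_order_estimate(ground.eps, guess.f)

state_c, eps_c, _, n_c, _ = run_constrained(guess, backend, [exc],
                                            eps_guess=ground.eps)
order_pc = saddle_order(np.linalg.eigvalsh(numeric_hessian(state_c, backend)))
diag_pc = diagonal_order_estimate(eps_c, state_c.f)

final = run_released(state_c, backend, eps_refreshed=eps_c)
eigs = np.linalg.eigvalsh(numeric_hessian(final.state, backend))
order_final = saddle_order(eigs)

print("saddle-order estimates (numeric Hessian / diagonal model):")
print(f"  at ground-orbital guess : {order_guess} / {diag_guess}")
print(f"  after constrained step  : {order_pc} / {diag_pc}")
print(f"  at converged solution   : {order_final}  (the true order)")
print(f"negative eigenvalues at the solution (eV): "
      f"{np.round(eigs[eigs < 0] * HARTREE_TO_EV, 3)}")
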