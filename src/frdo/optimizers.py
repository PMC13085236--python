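"""Limited-memory quasi-Newton steppers for orbital rotations.

Two steppers are provided: L-BFGS for the minimization phases (ground
state and constrained optimization) and L-SR1, which can represent an
indefinite inverse Hessian, for the saddle-point search after release.
Both start from a diagonal preconditioner built from the orbital-energy
Hessian approximation and use a fixed maximum step size instead of a
line search.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuasiNewtonState",
    "make_preconditioner",
    "clip_step",
    "lbfgs_step",
    "lsr1_step",
]


@dataclass
class QuasiNewtonState:
    """Memory and settings of a limited-memory quasi-Newton stepper."""

    precond: np.ndarray          # signed inverse-diagonal initial Hessian
    max_step: float              # cap on the max-norm of each step
    m: int = 20                  # memory length
    skip_tol: float = 1e-8       # SR1 update skip tolerance
    memory: deque = field(default_factory=deque)  # (s, y) pairs
    iteration: int = 0

    def __post_init__(self):
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        self.memory = deque(self.memory, maxlen=self.m)

    def push(self, s: np.ndarray, y: np.ndarray) -> None:
        self.memory.append((np.asarray(s, float), np.asarray(y, float)))


def make_preconditioner(d: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Signed inverse diagonal 1/d with |d| floored; sign preserved.

    Negative elements are kept negative: for the L-SR1 saddle search they
    drive the initial step uphill along concave directions.  Zero
    elements (redundant rotations) get the positive floor.
    """
    d = np.asarray(d, dtype=float)
    sign = np.where(d < 0, -1.0, 1.0)
    return sign / np.maximum(np.abs(d), floor)


def clip_step(step: np.ndarray, max_step: float) -> np.ndarray:
    """Uniformly rescale so the max-norm does not exceed max_step."""
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    step = np.asarray(step, dtype=float)
    mx = np.max(np.abs(step)) if step.size else 0.0
    if mx > max_step:
        return step * (max_step / mx)
    return step


def lbfgs_step(qn: QuasiNewtonState, g: np.ndarray) -> np.ndarray:
    """Two-loop-recursion L-BFGS step -H g, capped.

    Minimization context: the initial inverse Hessian is the absolute
    value of the preconditioner (negative curvature must not be followed
    downhill-in-|g| when minimizing), and updates violating the curvature
    condition are skipped.
    """
    g = np.asarray(g, dtype=float)
    h0 = np.abs(qn.precond)
    pairs = [(s, y, float(np.dot(s, y))) for s, y in qn.memory]
    pairs = [(s, y, sy) for s, y, sy in pairs
             if sy > 1e-10 * np.linalg.norm(s) * np.linalg.norm(y)]
    q = g.copy()
    alphas = []
    for s, y, sy in reversed(pairs):
        a = np.dot(s, q) / sy
        q -= a * y
        alphas.append(a)
    r = h0 * q
    for (s, y, sy), a in zip(pairs, reversed(alphas)):
        b = np.dot(y, r) / sy
        r += (a - b) * s
    return clip_step(-r, qn.max_step)


def _sr1_inverse(qn: QuasiNewtonState, n: int) -> np.ndarray:
    """Dense inverse-Hessian approximation from sequential SR1 updates.

    Rotation spaces are small, so the dense n x n form is built directly;
    an update is skipped when |(s - H y)^T y| < tol ||s - H y|| ||y||.
    """
    H = np.diag(qn.precond[:n] if qn.precond.size >= n else
                np.full(n, qn.precond))
    for s, y in qn.memory:
        u = s - H @ y
        d = float(np.dot(u, y))
        if abs(d) >= qn.skip_tol * np.linalg.norm(u) * np.linalg.norm(y) and d != 0.0:
            H = H + np.outer(u, u) / d
    return H


def lsr1_step(qn: QuasiNewtonState, g: np.ndarray) -> np.ndarray:
    """L-SR1 step -H g with the signed (possibly indefinite) H, capped."""
    g = np.asarray(g, dtype=float)
    if not qn.memory:
        return clip_step(-qn.precond * g, qn.max_step)
    H = _sr1_inverse(qn, g.size)
    return clip_step(-(H @ g), qn.max_step)
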