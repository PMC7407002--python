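"""Exact propagation helpers for linear time-invariant compartment systems.

All insulin subsystems in this package (subcutaneous depots, plasma/liver
kinetics) are linear ODE systems driven by impulsive doses and piecewise
inputs, so matrix-exponential propagation between events is exact up to
floating point.  These helpers centralise that machinery.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


def step_matrix(A: np.ndarray, dt: float) -> np.ndarray:
    """Exact one-step propagator ``expm(A * dt)``."""
    return expm(np.asarray(A, dtype=float) * dt)


def foh_input_matrices(A: np.ndarray, b: np.ndarray, dt: float):
    """First-order-hold discretisation of ``dx/dt = A x + b u(t)``.

    Returns ``(Phi, B0, B1)`` such that, for an input that is linear in
    time between grid points,

        x[k+1] = Phi @ x[k] + B0 * u[k] + B1 * u[k+1]

    reproduces the continuous solution exactly.  Requires ``A`` invertible
    (true for any strictly stable compartment system).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    phi = expm(A * dt)
    eye = np.eye(A.shape[0])
    Ainv = np.linalg.inv(A)
    J0 = Ainv @ (phi - eye)            # int_0^dt expm(A t) dt
    J1 = Ainv @ (phi * dt - J0)        # int_0^dt expm(A t) t dt
    B0 = (J1 / dt) @ b
    B1 = (J0 - J1 / dt) @ b
    return phi, B0, B1


def impulse_train_grid(
    A: np.ndarray,
    x0: np.ndarray,
    step: float,
    n_steps: int,
    impulses: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Propagate ``dx/dt = A x`` on a uniform grid with impulsive additions.

    ``impulses`` maps grid index -> state increment applied immediately
    *before* propagating away from that grid point (i.e. the sampled state
    at an injection index includes the fresh dose).  Returns an array of
    shape ``(n_steps + 1, len(x0))`` with the state at every grid point.
    """
    x = np.array(x0, dtype=float)
    out = np.empty((n_steps + 1, x.size))
    M = step_matrix(A, step)
    impulses = impulses or {}
    for k in range(n_steps + 1):
        if k in impulses:
            x = x + impulses[k]
        out[k] = x
        if k < n_steps:
            x = M @ x
    return out


def periodic_predose_state(A: np.ndarray, d: np.ndarray, period: float) -> np.ndarray:
    """Pre-dose state of the periodic steady state under repeated impulses ``d``.

    Solves ``s = E (s + d)`` with ``E = expm(A * period)``: the state just
    before each dose once accumulation from an infinite train of identical,
    equally spaced doses has converged.
    """
    E = step_matrix(A, period)
    n = E.shape[0]
    return np.linalg.solve(np.eye(n) - E, E @ np.asarray(d, dtype=float))
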