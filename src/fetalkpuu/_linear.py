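"""Exact propagation of linear dosing systems.

The reduced disposition models here are linear and time-invariant, so a
multiple-dose profile and the periodic steady state are computed exactly with
matrix exponentials instead of repeated numerical integration:

    x'(t) = A x(t) + u(t),   x(0+) = x(0) + b at each dose time,

with ``b`` the bolus amount vector (e.g. an oral dose entering the gut
compartment) and ``u`` a constant infusion-rate vector active for
``infusion_dur`` hours after each dose. Over one grid step dt the update is
``x -> E x + K u`` with E = expm(A dt), K = A^{-1}(E - I); the pre-dose
steady-state amounts solve (I - expm(A tau)) x0 = (contribution of one dose).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

__all__ = ["dosing_profile", "steady_state_profile"]


def _grid_steps(duration: float, dt: float) -> int:
    n = int(round(duration / dt))
    if abs(n * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValueError(f"duration {duration} is not a multiple of grid step {dt}")
    return n


def _step_operators(A: np.ndarray, dt: float):
    E = expm(A * dt)
    K = np.linalg.solve(A, E - np.eye(A.shape[0]))
    return E, K


def _one_interval(x, E, K, u, n_inf, n_rest, out):
    """Propagate one dosing interval, appending post-step states to ``out``."""
    for _ in range(n_inf):
        x = E @ x + K @ u
        out.append(x)
    for _ in range(n_rest):
        x = E @ x
        out.append(x)
    return x


def dosing_profile(
    A: np.ndarray,
    bolus: np.ndarray,
    infusion: np.ndarray | None,
    infusion_dur: float,
    interval: float,
    n_doses: int,
    dt: float = 0.1,
    washout: float = 0.0,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Amount profile over ``n_doses`` doses plus ``washout`` hours.

    Returns (t, X) with X[i] the state-amount vector at t[i]; t starts at 0
    (the instant of the first dose, post-bolus state at index 0).
    """
    n = A.shape[0]
    u = np.zeros(n) if infusion is None else np.asarray(infusion, dtype=float)
    b = np.asarray(bolus, dtype=float)
    n_int = _grid_steps(interval, dt)
    n_inf = _grid_steps(infusion_dur, dt) if np.any(u) else 0
    if n_inf > n_int:
        raise ValueError("infusion duration exceeds the dosing interval")
    n_rest = n_int - n_inf
    n_wash = _grid_steps(washout, dt) if washout else 0

    E, K = _step_operators(A, dt)
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    states = []
    for _ in range(n_doses):
        x = x + b
        states.append(x)
        x = _one_interval(x, E, K, u, n_inf, n_rest, states)
        states.pop()  # dose boundary: keep the post-bolus state of the next dose
    states.append(x)
    if n_wash:
        x = _one_interval(x, E, K, np.zeros(n), 0, n_wash, states)
    X = np.array(states)
    t = np.arange(X.shape[0]) * dt
    return t, X


def steady_state_profile(
    A: np.ndarray,
    bolus: np.ndarray,
    infusion: np.ndarray | None,
    infusion_dur: float,
    interval: float,
    dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact periodic steady-state amount profile over one dosing interval.

    Solves (I - expm(A tau)) x0 = (state gained from one dose over one
    interval) for the pre-dose amounts, then propagates on the grid.
    Requires A to be Hurwitz (every compartment ultimately drains), which
    holds for any model with nonzero systemic clearance.
    """
    n = A.shape[0]
    u = np.zeros(n) if infusion is None else np.asarray(infusion, dtype=float)
    b = np.asarray(bolus, dtype=float)
    n_int = _grid_steps(interval, dt)
    n_inf = _grid_steps(infusion_dur, dt) if np.any(u) else 0
    n_rest = n_int - n_inf
    E, K = _step_operators(A, dt)

    # state at interval end starting from zero with one dose administered
    gain = _one_interval(b.copy(), E, K, u, n_inf, n_rest, out=[])
    E_tau = expm(A * interval)
    x0 = np.linalg.solve(np.eye(n) - E_tau, gain)

    states = [x0 + b]
    _one_interval(x0 + b, E, K, u, n_inf, n_rest, states)
    X = np.array(states)
    t = np.arange(X.shape[0]) * dt
    return t, X
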