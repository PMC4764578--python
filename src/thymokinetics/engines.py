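"""Independent verification engines for the compartment model.

Two routes that share nothing with the closed forms:

* :func:`integrate_ode` — adaptive stiff-safe numerical integration of the
  deterministic rate equations (scipy ``solve_ivp``, LSODA).
* :func:`simulate_ssa` — an exact stochastic simulation (Gillespie direct
  method) of the underlying jump process, in which individual cells flow in,
  differentiate and die as discrete events.  Because all rates are per-cell,
  trajectories at a reduced population scale are statistically faithful and
  cheap; their mean converges to the ODE solution by the law of large
  numbers.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .exceptions import ValidationError
from .model import CompartmentState, RateParameters, TimeCourse

__all__ = ["integrate_ode", "simulate_ssa", "default_acd3_grid"]


def default_acd3_grid(days: float = 3.0, dt: float = 0.125) -> np.ndarray:
    """The standard anti-CD3 simulation grid: 3-hour (0.125-day) steps."""
    n = int(round(days / dt))
    return np.linspace(0.0, n * dt, n + 1)


def integrate_ode(
    params: RateParameters,
    c0: CompartmentState,
    t_grid: np.ndarray,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-6,
) -> TimeCourse:
    """Numerically integrate the rate equations on an output grid.

    ``t_grid`` must be strictly increasing and start at ``c0.t``.  The grid
    only controls where the solution is reported; the integrator chooses its
    internal steps adaptively.  ``rel_tol`` must lie in (0, 1e-3].
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be non-empty and strictly increasing")
    if t_grid[0] != c0.t:
        raise ValidationError(
            f"t_grid must start at the initial time {c0.t}, got {t_grid[0]}"
        )
    if not (0 < rel_tol <= 1e-3):
        raise ValidationError(f"rel_tol must be in (0, 1e-3], got {rel_tol}")

    A = params.system_matrix()
    b = np.array([params.K, 0.0, 0.0, 0.0])

    if t_grid.size == 1:
        counts = c0.counts[None, :]
    else:
        sol = solve_ivp(
            lambda t, y: A @ y + b,
            (t_grid[0], t_grid[-1]),
            c0.counts,
            t_eval=t_grid,
            method="LSODA",
            jac=lambda t, y: A,
            rtol=rel_tol,
            atol=abs_tol,
        )
        if not sol.success:  # pragma: no cover - LSODA handles linear systems
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        counts = sol.y.T
    # tolerate integrator roundoff at the level of abs_tol, never real negativity
    if np.any(counts < -10 * abs_tol):
        raise ArithmeticError("ODE solution genuinely negative; check parameters")
    counts = np.clip(counts, 0.0, None)
    return TimeCourse(t_grid, counts, engine="ode", label=params.label)


# reaction index -> (compartment gaining, compartment losing); -1 = none
# 0: influx -> DN3        1: DN3 -> DN4        2: DN3 death
# 3: DN4 -> ISP           4: DN4 death         5: ISP -> DP
# 6: ISP death            7: DP death
@njit(cache=False)
def _ssa_core(rates, c_init, t_grid, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    K, K1, Kd1, K2, Kd2, K3, Kd3, Kd4 = rates
    c = c_init.copy()
    out = np.zeros((t_grid.size, 4), dtype=np.int64)
    n_events = 0
    t = 0.0
    gi = 0
    a = np.empty(8)
    while gi < t_grid.size:
        a[0] = K
        a[1] = K1 * c[0]
        a[2] = Kd1 * c[0]
        a[3] = K2 * c[1]
        a[4] = Kd2 * c[1]
        a[5] = K3 * c[2]
        a[6] = Kd3 * c[2]
        a[7] = Kd4 * c[3]
        atot = a.sum()
        if atot <= 0.0:
            break  # absorbing: nothing can fire any more
        t_next = t + np.random.exponential(1.0 / atot)
        while gi < t_grid.size and t_grid[gi] < t_next:
            out[gi] = c
            gi += 1
        t = t_next
        r = np.random.random() * atot
        acc = 0.0
        j = 0
        for k in range(8):
            acc += a[k]
            if r < acc:
                j = k
                break
        if j == 0:
            c[0] += 1
        elif j == 1:
            c[0] -= 1
            c[1] += 1
        elif j == 2:
            c[0] -= 1
        elif j == 3:
            c[1] -= 1
            c[2] += 1
        elif j == 4:
            c[1] -= 1
        elif j == 5:
            c[2] -= 1
            c[3] += 1
        elif j == 6:
            c[2] -= 1
        else:
            c[3] -= 1
        n_events += 1
    while gi < t_grid.size:
        out[gi] = c
        gi += 1
    return out, n_events


def simulate_ssa(
    params: RateParameters,
    c0: CompartmentState | np.ndarray,
    t_max: float,
    seed: int,
    t_grid: np.ndarray | None = None,
    record_dt: float = 0.125,
) -> TimeCourse:
    """Exact stochastic trajectory of the cell-level jump process.

    Reactions: influx (rate K), per-cell differentiation DN3->DN4 (K1),
    DN4->ISP (K2), ISP->DP (K3) and per-cell loss (Kd1..Kd4).  The state is
    recorded at the requested grid times (default 0.125-day spacing up to
    ``t_max``); between events populations are piecewise constant.  Identical
    (params, c0, grid, seed) give a bit-identical trajectory.

    ``c0`` must hold integer counts (cells are discrete here).
    """
    counts0 = c0.counts if isinstance(c0, CompartmentState) else np.asarray(c0, float)
    if counts0.shape != (4,) or np.any(counts0 < 0):
        raise ValidationError("c0 must be 4 non-negative counts")
    if np.any(counts0 != np.round(counts0)):
        raise ValidationError("SSA initial counts must be integers (discrete cells)")
    if not isinstance(seed, (int, np.integer)) or not (0 <= int(seed) < 2**32):
        raise ValidationError("seed must be an integer in [0, 2^32)")
    if t_grid is None:
        if t_max <= 0:
            raise ValidationError("t_max must be > 0")
        n = max(1, int(round(t_max / record_dt)))
        t_grid = np.linspace(0.0, t_max, n + 1)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValidationError("t_grid must be non-negative and strictly increasing")

    rates = np.array(
        [params.K, params.K1, params.Kd1, params.K2, params.Kd2,
         params.K3, params.Kd3, params.Kd4]
    )
    out, _ = _ssa_core(rates, counts0.astype(np.int64), t_grid, int(seed))
    return TimeCourse(
        t_grid, out.astype(float), engine="ssa", label=params.label, seed=int(seed)
    )
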