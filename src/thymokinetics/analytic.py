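"""Closed-form solutions of the four-compartment beta-selection model.

Three solution routes are provided:

* :func:`steady_state_exact` — the fixed point of the full linear system with
  constant influx, as a product of branching ratios.
* :func:`steady_state_approx` — the simplified fixed point valid when DN4 and
  ISP turnover is negligible relative to their differentiation rates
  (K2/(K2+Kd2) ~ 1, K3/(K3+Kd3) ~ 1).
* :func:`transient_solution` — the explicit sum-of-exponentials solution of
  the influx-free system (K = 0, Kd2 = Kd3 = 0) started from a pure DN3 pool,
  the anti-CD3-injected Rag2-deficient scenario.  Near-degenerate rate
  constants (repeated eigenvalues) make the explicit form numerically
  catastrophic, so those cases — and any case the explicit form does not
  cover — dispatch to :func:`spectral_solution`, an exact matrix-exponential
  solution of the general affine system.

All times are in days, rates in 1/day, populations in cells.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.linalg import expm

from .exceptions import SteadyStateError, ValidationError
from .model import CompartmentState, RateParameters, TimeCourse

__all__ = [
    "steady_state_exact",
    "steady_state_approx",
    "transient_solution",
    "spectral_solution",
    "solve_timecourse",
    "dn4_peak_time",
    "DEGENERACY_RTOL",
]

logger = logging.getLogger(__name__)

#: Two rates a, b are treated as numerically equal (degenerate) when
#: |a - b| <= DEGENERACY_RTOL * max(a, b, 1/day).
DEGENERACY_RTOL = 1e-9


def _is_degenerate(rates: np.ndarray) -> bool:
    r = np.asarray(rates, dtype=float)
    for i in range(r.size):
        for j in range(i + 1, r.size):
            if abs(r[i] - r[j]) <= DEGENERACY_RTOL * max(r[i], r[j], 1.0):
                return True
    return False


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

def steady_state_exact(params: RateParameters) -> CompartmentState:
    """Exact steady state of the model with constant influx.

    Each compartment holds influx divided by its exit rate::

        C1 = K / (K1+Kd1)
        C2 = K K1 / ((K1+Kd1)(K2+Kd2))
        C3 = K K1 K2 / ((K1+Kd1)(K2+Kd2)(K3+Kd3))
        C4 = K K1 K2 K3 / (Kd4 (K1+Kd1)(K2+Kd2)(K3+Kd3))

    The returned state carries ``t = inf`` as an explicit steady-state marker.

    Raises
    ------
    SteadyStateError
        If Kd4 = 0 while influx feeds the DP compartment (it would grow
        without bound).
    ValidationError
        If an upstream exit rate is zero while K > 0.
    """
    if params.K == 0:
        return CompartmentState(math.inf, 0.0, 0.0, 0.0, 0.0)
    a1, a2, a3, a4 = params.exit_rates
    if a1 <= 0 or a2 <= 0 or a3 <= 0:
        raise ValidationError(
            "steady state undefined: a compartment exit rate (K1+Kd1, K2+Kd2, "
            "K3+Kd3) is zero while influx K > 0"
        )
    if a4 <= 0 and params.K3 > 0 and params.K1 > 0 and params.K2 > 0:
        raise SteadyStateError(
            "no finite steady state for DP: Kd4 = 0 while K > 0 feeds the "
            "DP compartment"
        )
    c1 = params.K / a1
    c2 = c1 * params.K1 / a2
    c3 = c2 * params.K2 / a3
    c4 = 0.0 if c3 * params.K3 == 0 else c3 * params.K3 / a4
    return CompartmentState(math.inf, c1, c2, c3, c4)


def steady_state_approx(params: RateParameters) -> CompartmentState:
    """Simplified steady state assuming negligible DN4/ISP turnover.

    Valid when Kd2 << K2 and Kd3 << K3, so that essentially every DN4 cell
    becomes an ISP and every ISP a DP::

        C1 ~ K / (K1+Kd1)
        C2 ~ K K1 / (K2 (K1+Kd1))
        C3 ~ K K1 / (K3 (K1+Kd1))
        C4 ~ K K1 / (Kd4 (K1+Kd1))
    """
    a1 = params.k1_tilde
    if a1 <= 0:
        raise ValidationError("K1 + Kd1 must be > 0")
    for name in ("K2", "K3", "Kd4"):
        if getattr(params, name) <= 0:
            raise ValidationError(f"{name} must be > 0 for the simplified steady state")
    c1 = params.K / a1
    base = params.K * params.K1 / a1
    return CompartmentState(
        math.inf, c1, base / params.K2, base / params.K3, base / params.Kd4
    )


# ---------------------------------------------------------------------------
# Transient solution (anti-CD3 scenario, K = 0)
# ---------------------------------------------------------------------------

def _transient_counts(params: RateParameters, c10: float, t: np.ndarray) -> np.ndarray:
    """Explicit sum-of-exponentials solution from (c10, 0, 0, 0); K = 0.

    Terms are grouped exactly as in the hand-derived solution so each line
    can be checked against it term by term.  Caller guarantees distinct
    rates and Kd2 = Kd3 = 0.
    """
    K1, K2, K3, Kd4 = params.K1, params.K2, params.K3, params.Kd4
    a1 = params.k1_tilde  # total DN3 exit rate

    e1 = np.exp(-a1 * t)
    e2 = np.exp(-K2 * t)
    e3 = np.exp(-K3 * t)
    e4 = np.exp(-Kd4 * t)

    c1 = c10 * e1
    c2 = K1 * c10 / (K2 - a1) * (e1 - e2)
    c3 = (
        K1 * K2 * c10 / (K2 - a1)
        * (
            e1 / (K3 - a1)
            - e2 / (K3 - K2)
            + (K2 - a1) * e3 / ((K3 - a1) * (K3 - K2))
        )
    )
    bracket_t = (
        e1 / ((Kd4 - a1) * (K3 - a1))
        - e2 / ((K3 - K2) * (Kd4 - K2))
        + (K2 - a1) * e3 / ((K3 - a1) * (K3 - K2) * (Kd4 - K3))
    )
    bracket_0 = (
        1.0 / ((Kd4 - a1) * (K3 - a1))
        - 1.0 / ((K3 - K2) * (Kd4 - K2))
        + (K2 - a1) / ((K3 - a1) * (K3 - K2) * (Kd4 - K3))
    )
    c4 = K1 * K2 * K3 * c10 / (K2 - a1) * (bracket_t - bracket_0 * e4)
    return np.column_stack([c1, c2, c3, c4])


def _snap_roundoff(counts: np.ndarray, scale: float) -> np.ndarray:
    """Zero out negative values attributable to floating-point cancellation.

    A value more negative than -1e-9 * scale indicates a genuine defect and
    raises instead of being hidden.
    """
    floor = -1e-9 * max(scale, 1.0)
    if np.any(counts < floor):
        raise ArithmeticError(
            f"closed-form solution produced a genuinely negative population "
            f"(min {counts.min():g}); parameters may be outside the valid regime"
        )
    return np.where((counts < 0) & (counts >= floor), 0.0, counts)


def transient_solution(
    params: RateParameters, c0: CompartmentState, t: float
) -> CompartmentState:
    """Closed-form state at time ``t`` for the influx-free (K = 0) model.

    Models the anti-CD3 time course in recombination-deficient mice: a pure
    DN3 pool of size C1(0) differentiates synchronously down the chain with
    no progenitor influx.  Requires K = 0.  The explicit formula additionally
    assumes Kd2 = Kd3 = 0, empty downstream compartments at t = 0 and
    pairwise-distinct decay rates {K1+Kd1, K2, K3, Kd4}; other cases are
    dispatched to :func:`spectral_solution`, which solves the same system
    exactly.
    """
    if params.K > 0:
        raise ValidationError(
            "transient_solution requires K = 0 (no progenitor influx); use "
            "spectral_solution or the ODE engine for K > 0"
        )
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    if t == 0:
        return c0
    rates = np.array([params.k1_tilde, params.K2, params.K3, params.Kd4])
    needs_spectral = (
        _is_degenerate(rates)
        or params.Kd2 > 0
        or params.Kd3 > 0
        or c0.C2 > 0
        or c0.C3 > 0
        or c0.C4 > 0
    )
    if needs_spectral:
        logger.info(
            "transient_solution: dispatching to spectral_solution "
            "(degenerate rates or non-zero downstream initial state)"
        )
        return spectral_solution(params, c0, t)
    counts = _transient_counts(params, c0.C1, np.atleast_1d(float(t)))
    counts = _snap_roundoff(counts, c0.C1)
    return CompartmentState.from_counts(t, counts[0])


# ---------------------------------------------------------------------------
# General spectral / matrix-exponential solution
# ---------------------------------------------------------------------------

def _spectral_counts(
    params: RateParameters, c0_counts: np.ndarray, t: np.ndarray
) -> np.ndarray:
    # Affine system dC/dt = A C + b solved via the augmented matrix
    # M = [[A, b], [0, 0]]:  (C(t), 1) = expm(M t) (C0, 1).  Exact for any
    # rate constants, including repeated eigenvalues and singular A.
    M = np.zeros((5, 5))
    M[:4, :4] = params.system_matrix()
    M[0, 4] = params.K
    z = np.append(np.asarray(c0_counts, dtype=float), 1.0)
    out = np.empty((t.size, 4))
    for i, ti in enumerate(t):
        out[i] = (expm(M * ti) @ z)[:4]
    return out


def spectral_solution(
    params: RateParameters, c0: CompartmentState, t: float
) -> CompartmentState:
    """Exact solution of the full affine system at time ``t``.

    Valid for any non-negative rate constants (K > 0, repeated rates,
    non-zero downstream initial populations).  Agrees with
    :func:`transient_solution` in its domain and converges to
    :func:`steady_state_exact` as t grows.
    """
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    counts = _spectral_counts(params, c0.counts, np.atleast_1d(float(t)))
    counts = _snap_roundoff(counts, max(float(np.max(c0.counts)), params.K))
    return CompartmentState.from_counts(t, counts[0])


def solve_timecourse(
    params: RateParameters,
    c0: CompartmentState,
    times: np.ndarray,
    method: str = "auto",
) -> TimeCourse:
    """Evaluate the analytic solution on a time grid.

    ``method`` is "auto" (explicit formula where valid, spectral otherwise),
    "transient" or "spectral".  ``times`` must be non-negative and strictly
    increasing; ``c0.t`` must be 0.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be a non-empty strictly increasing 1-D grid")
    if times[0] < 0:
        raise ValidationError("times must be non-negative")
    if c0.t != 0:
        raise ValidationError("initial state must have t = 0")

    rates = np.array([params.k1_tilde, params.K2, params.K3, params.Kd4])
    explicit_ok = (
        params.K == 0
        and params.Kd2 == 0
        and params.Kd3 == 0
        and c0.C2 == 0
        and c0.C3 == 0
        and c0.C4 == 0
        and not _is_degenerate(rates)
    )
    if method == "transient" and not explicit_ok:
        raise ValidationError(
            "explicit transient formula not applicable (needs K = 0, "
            "Kd2 = Kd3 = 0, pure DN3 start, distinct rates)"
        )
    use_explicit = explicit_ok if method == "auto" else method == "transient"
    if method not in ("auto", "transient", "spectral"):
        raise ValidationError(f"unknown method {method!r}")

    if use_explicit:
        counts = _transient_counts(params, c0.C1, times)
        scale = c0.C1
    else:
        counts = _spectral_counts(params, c0.counts, times)
        scale = max(float(np.max(c0.counts)), params.K)
    counts = _snap_roundoff(counts, scale)
    # splice in the exact initial state at t = 0
    if times[0] == 0:
        counts[0] = c0.counts
    return TimeCourse(times, counts, engine="analytic", label=params.label)


def dn4_peak_time(params: RateParameters) -> float:
    """Time (days) at which the DN4 population peaks in the K = 0 scenario.

    The DN4 curve is proportional to exp(-(K1+Kd1) t) - exp(-K2 t); its
    maximizer is ln(K2/(K1+Kd1)) / (K2 - (K1+Kd1)), with limit 1/K2 when
    the two rates coincide.  Faster differentiation peaks earlier.
    """
    if params.K > 0:
        raise ValidationError("dn4_peak_time applies to the influx-free (K = 0) model")
    a1 = params.k1_tilde
    K2 = params.K2
    if a1 <= 0 or K2 <= 0:
        raise ValidationError("K1 + Kd1 and K2 must be > 0")
    if abs(K2 - a1) <= DEGENERACY_RTOL * max(K2, a1, 1.0):
        return 1.0 / K2
    return math.log(K2 / a1) / (K2 - a1)
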