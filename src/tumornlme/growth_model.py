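"""Gompertz tumour-growth structural model with a multiplicative treatment effect.

The tumour volume V(t) (mm^3) grows towards a plateau ``v_max`` according to
the generalized Gompertz law

    dV/dt = k_eff(t) * V * [ln(v_max / V)]**gamma ,   V(0) = v0,

where ``k_eff`` equals the intrinsic first-order rate constant ``k_growth``
(1/day) off treatment and ``k_growth * (1 - eff)`` while an antagonist
treatment is active (``eff`` = 0 means no effect; ``eff`` = 1 means growth
arrest).  ``gamma`` is a dimensionless power coefficient; the classic
Gompertz model is recovered at gamma = 1.

Substituting u = ln(v_max / V) turns the ODE into the separable
du/dt = -k_eff * u**gamma, which integrates in closed form:

    gamma == 1 :  u(t) = u0 * exp(-k_eff t)
    gamma != 1 :  u(t)**(1-gamma) = u0**(1-gamma) - (1-gamma) k_eff t

(for gamma < 1 the plateau u = 0 is reached in finite time and the solution
continues at the V = v_max equilibrium).  The default predictor uses this
exact solution; an adaptive Runge-Kutta integration is available as an
independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GompertzParams",
    "TreatmentSchedule",
    "CaliperMeasurement",
    "volume_from_caliper",
    "effective_growth_rate",
    "predict_volume",
    "time_to_volume",
]


@dataclass(frozen=True)
class GompertzParams:
    """Individual-level parameters of the generalized Gompertz model.

    Attributes
    ----------
    k_growth : float
        First-order growth rate constant, 1/day.
    v_max : float
        Maximum (plateau) tumour volume, mm^3.
    gamma : float
        Dimensionless power coefficient on ln(v_max/V).
    eff : float
        Multiplicative treatment effect on the growth rate; 0 = no effect.
    v0 : float
        Volume at the time origin (treatment start), mm^3.
    """

    k_growth: float
    v_max: float
    gamma: float
    eff: float = 0.0
    v0: float = 80.0

    def __post_init__(self) -> None:
        if not (self.k_growth > 0):
            raise ValueError(f"k_growth must be > 0, got {self.k_growth}")
        if not (self.v_max > 0):
            raise ValueError(f"v_max must be > 0, got {self.v_max}")
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (self.eff >= 0):
            raise ValueError(f"eff must be >= 0, got {self.eff}")
        if not (self.v0 > 0):
            raise ValueError(f"v0 must be > 0, got {self.v0}")
        if self.v0 > self.v_max:
            raise ValueError(
                f"v0 ({self.v0}) must not exceed v_max ({self.v_max})"
            )


@dataclass(frozen=True)
class TreatmentSchedule:
    """Treatment design metadata for one animal.

    ``start_time`` is the day (on the trajectory clock) the antagonist is
    first given; the drug effect is modelled as continuously on from then.
    ``dosing_interval`` (every two days i.p. in the emulated design) is kept
    as metadata only -- no pharmacokinetics is modelled.
    """

    treated: bool
    start_time: float = 0.0
    dosing_interval: float = 2.0

    def __post_init__(self) -> None:
        if not (self.start_time >= 0):
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if not (self.dosing_interval > 0):
            raise ValueError(
                f"dosing_interval must be > 0, got {self.dosing_interval}"
            )


@dataclass(frozen=True)
class CaliperMeasurement:
    """Two perpendicular tumour diameters (mm): longest L and width l."""

    L: float
    l: float

    def __post_init__(self) -> None:
        if self.l < 0 or self.L < 0:
            raise ValueError("caliper diameters must be non-negative")
        if self.L < self.l:
            raise ValueError(f"L ({self.L}) must be >= l ({self.l})")


def volume_from_caliper(m: CaliperMeasurement) -> float:
    """Ellipsoid-approximation tumour volume (L * l^2) / 2 in mm^3."""
    return m.L * m.l**2 / 2.0


def effective_growth_rate(
    k_growth: float,
    eff: float,
    treated: bool,
    *,
    allow_shrinkage: bool = False,
) -> float:
    """Growth rate under the treatment model: k*(1-eff) on treatment, k off.

    The untreated/treated rate ratio is 1/(1-eff).  ``eff >= 1`` under
    treatment (zero or negative net growth, i.e. tumour shrinkage) is only
    allowed with ``allow_shrinkage=True``.
    """
    if not (k_growth > 0):
        raise ValueError(f"k_growth must be > 0, got {k_growth}")
    if not (eff >= 0):
        raise ValueError(f"eff must be >= 0, got {eff}")
    if not treated:
        return k_growth
    if eff >= 1.0 and not allow_shrinkage:
        raise ValueError(
            f"eff = {eff} >= 1 under treatment implies shrinkage; "
            "pass allow_shrinkage=True to permit it"
        )
    return k_growth * (1.0 - eff)


# ---------------------------------------------------------------------------
# analytic solution core (vectorized; shared with the simulator and the
# SAEM estimator, where it is evaluated for whole cohorts at once)
# ---------------------------------------------------------------------------


def _advance_u(u0, k, dt, gamma):
    """Evolve u = ln(v_max/V) forward by dt >= 0 under du/dt = -k u**gamma.

    Broadcasts over arrays.  u0 = 0 is an equilibrium and stays 0.  For
    gamma < 1 the solution reaching u = 0 is continued at 0 (plateau); for
    gamma > 1 with k < 0 the blow-up u -> inf (V -> 0) is clamped.
    """
    u0 = np.asarray(u0, dtype=float)
    k = np.asarray(k, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if gamma == 1.0:
        u = u0 * np.exp(-k * dt)
        return np.where(u0 <= 0.0, 0.0, u)
    om = 1.0 - gamma
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        base = np.where(u0 > 0.0, u0, 1.0) ** om
        w = base - om * k * dt
        if om > 0:
            w = np.maximum(w, 0.0)
        else:
            w = np.maximum(w, 1e-300)
        u = w ** (1.0 / om)
    return np.where(u0 <= 0.0, 0.0, u)


def _volumes(times, k, v_max, gamma, eff, v0, start_time=0.0):
    """Vectorized exact trajectories of the generalized Gompertz model.

    Parameters broadcast against ``times``; treatment (rate ``k*(1-eff)``)
    is on for t > start_time.  Pass eff = 0 for untreated trajectories.
    """
    times = np.asarray(times, dtype=float)
    u0 = np.log(np.asarray(v_max, dtype=float) / np.asarray(v0, dtype=float))
    k = np.asarray(k, dtype=float)
    k_post = k * (1.0 - np.asarray(eff, dtype=float))
    pre = times <= start_time
    u_pre = _advance_u(u0, k, np.maximum(times, 0.0), gamma)
    u_start = _advance_u(u0, k, start_time, gamma)
    u_post = _advance_u(u_start, k_post, np.maximum(times - start_time, 0.0), gamma)
    u = np.where(pre, u_pre, u_post)
    return v_max * np.exp(-u)


def _predict_ode(p, sched, times, rtol, atol):
    k_pre = p.k_growth
    k_post = effective_growth_rate(
        p.k_growth, p.eff, sched.treated, allow_shrinkage=True
    )

    def rhs(k):
        def f(t, y):
            v = min(max(y[0], 1e-12), p.v_max)
            u = math.log(p.v_max / v)
            return [k * v * max(u, 0.0) ** p.gamma]

        return f

    out = np.empty(times.shape, dtype=float)
    t_break = sched.start_time if sched.treated else math.inf
    v = p.v0
    t_cur = 0.0
    # segment 1: pre-treatment
    pre_mask = times <= t_break
    if pre_mask.any():
        t_end = times[pre_mask][-1]
        sol = solve_ivp(
            rhs(k_pre),
            (0.0, max(t_end, 1e-12)),
            [p.v0],
            t_eval=times[pre_mask],
            rtol=rtol,
            atol=atol,
            method="RK45",
        )
        if not sol.success:
            raise RuntimeError(f"Gompertz ODE integration failed: {sol.message}")
        out[pre_mask] = sol.y[0]
    post_mask = ~pre_mask
    if post_mask.any():
        # advance the state to the treatment-start breakpoint first
        if t_break > 0:
            sol = solve_ivp(
                rhs(k_pre), (0.0, t_break), [p.v0], rtol=rtol, atol=atol,
                method="RK45",
            )
            if not sol.success:
                raise RuntimeError(
                    f"Gompertz ODE integration failed: {sol.message}"
                )
            v = sol.y[0][-1]
            t_cur = t_break
        sol = solve_ivp(
            rhs(k_post),
            (t_cur, times[post_mask][-1]),
            [v],
            t_eval=times[post_mask],
            rtol=rtol,
            atol=atol,
            method="RK45",
        )
        if not sol.success:
            raise RuntimeError(f"Gompertz ODE integration failed: {sol.message}")
        out[post_mask] = sol.y[0]
    return out


def predict_volume(
    p: GompertzParams,
    sched: TreatmentSchedule,
    times,
    *,
    method: str = "analytic",
    allow_shrinkage: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> np.ndarray:
    """Deterministic volume trajectory at the requested times (days).

    ``method="analytic"`` evaluates the exact closed-form solution (default);
    ``method="ode"`` integrates the ODE with adaptive Runge-Kutta, forcing
    the treatment-start time as a segment boundary, and serves as an
    independent numerical cross-check.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if times.size == 0:
        return np.empty(0)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if sched.treated and p.eff >= 1.0 and not allow_shrinkage:
        raise ValueError(
            f"eff = {p.eff} >= 1 under treatment implies shrinkage; "
            "pass allow_shrinkage=True to permit it"
        )
    if method == "analytic":
        eff = p.eff if sched.treated else 0.0
        return _volumes(
            times, p.k_growth, p.v_max, p.gamma, eff, p.v0, sched.start_time
        )
    if method == "ode":
        return _predict_ode(p, sched, times, rtol, atol)
    raise ValueError(f"unknown method {method!r}")


def _hit_time(u0: float, k: float, u_target: float, gamma: float):
    """Time for u to decay from u0 to u_target (< u0) at rate k > 0."""
    if u_target >= u0:
        return 0.0
    if k <= 0:
        return None
    if gamma == 1.0:
        return math.log(u0 / u_target) / k
    om = 1.0 - gamma
    return (u0**om - u_target**om) / (om * k)


def time_to_volume(
    p: GompertzParams, sched: TreatmentSchedule, v_target: float
):
    """First time the noise-free trajectory reaches ``v_target`` (mm^3).

    Returns None if the volume is never reached (target at or above the
    plateau, or growth arrested/reversed by treatment before crossing).
    Used to derive humane-endpoint survival times.
    """
    if not (v_target > 0):
        raise ValueError("v_target must be > 0")
    if v_target <= p.v0:
        return 0.0
    if v_target >= p.v_max:
        return None
    u_target = math.log(p.v_max / v_target)
    u0 = math.log(p.v_max / p.v0)
    t1 = _hit_time(u0, p.k_growth, u_target, p.gamma)
    if not sched.treated or (t1 is not None and t1 <= sched.start_time):
        return t1
    u_start = float(_advance_u(u0, p.k_growth, sched.start_time, p.gamma))
    k_post = p.k_growth * (1.0 - p.eff)
    t2 = _hit_time(u_start, k_post, u_target, p.gamma)
    if t2 is None:
        return None
    return sched.start_time + t2
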