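"""Structural model: covariate functions, ODE right-hand side, solver.

The five-state system (amounts in mg, calories in calorie-units)::

    dX1/dt = -kg_eff * X1
    dX2/dt =  kg_eff * X1 - kma_eff * X2
    dX3/dt =  kma_eff * X2 - k_el * X3
    dX4/dt = -kg' * X4
    dX5/dt =  kg' * X4 - k_out * X5

with ``kg_eff = kg * (1 + e_food)^w(t)`` (``w`` the post-meal food-window
indicator) and ``kma_eff = k_ma * (1 + e_bile * X5)``.  Measured
concentration is ``X3 / Vc_eff`` in mg/L == ug/mL.

The numerical solver integrates piecewise between bolus events and food
window boundaries with a stiff-capable adaptive method, restarting hard at
every discontinuity.  Closed-form solutions for the fasted drug cascade and
the calorie subsystem are provided as independent cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .events import EventSchedule, FoodType, StateVector
from .params import ModelParameters

__all__ = [
    "RandomEffects",
    "food_window_indicator",
    "effective_kg",
    "effective_kma",
    "effective_vc",
    "ode_rhs",
    "solve_profile",
    "ConcentrationProfile",
    "bateman_cascade",
    "calorie_profile",
    "derived_fed_parameters",
    "DerivedFedParameters",
]


class RandomEffects(NamedTuple):
    """One subject-occasion's log-scale deviates (all zero = typical)."""

    eta_kg: float = 0.0
    eta_kel: float = 0.0
    eta_vc: float = 0.0
    kappa_kel: float = 0.0
    kappa_vc: float = 0.0


# ---------------------------------------------------------------------------
# covariate functions
# ---------------------------------------------------------------------------

def food_window_indicator(
    t: float, meal_time: float, mtime1: float, mtime2: float, fed: bool
) -> int:
    """Post-meal window indicator: 1 iff fed and ``meal+mtime1 <= t < meal+mtime2``.

    Under fasted conditions the indicator is 0 at all times.  The window is
    half-open so consecutive regimes partition the time axis.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if not mtime2 > mtime1:
        raise ValueError("mtime2 must exceed mtime1")
    if not fed:
        return 0
    return int(meal_time + mtime1 <= t < meal_time + mtime2)


def effective_kg(tv_kg: float, e_food: float, indicator: int) -> float:
    """Gastric emptying rate of drug: ``tv_kg * (1 + e_food)**indicator``."""
    if tv_kg <= 0:
        raise ValueError("tv_kg must be positive")
    if e_food <= -1:
        raise ValueError("e_food must be > -1")
    return tv_kg * (1.0 + e_food) ** indicator


def effective_kma(k_ma: float, e_bile: float, x5: float) -> float:
    """Metabolism+absorption rate scaled by duodenal calories, linear in X5."""
    if k_ma <= 0:
        raise ValueError("k_ma must be positive")
    if x5 < 0:
        raise ValueError("x5 must be non-negative")
    out = k_ma * (1.0 + e_bile * x5)
    if out <= 0:
        raise ValueError("effective k_ma must stay positive")
    return out


def effective_vc(vc_over_f: float, food_type: FoodType,
                 e_vc1: float = -0.394, e_vc2: float = -0.461) -> float:
    """Apparent central volume under the occasion's food type."""
    if vc_over_f <= 0:
        raise ValueError("vc_over_f must be positive")
    food_type = FoodType(food_type)
    if food_type == FoodType.FASTED:
        factor = 1.0
    elif food_type == FoodType.STANDARD:
        factor = 1.0 + e_vc1
    elif food_type == FoodType.HIGH_FAT:
        factor = 1.0 + e_vc2
    else:  # pragma: no cover - FoodType() already rejects unknown codes
        raise ValueError(f"unknown food type: {food_type}")
    out = vc_over_f * factor
    if out <= 0:
        raise ValueError("effective Vc must stay positive")
    return out


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

def _window_indicator_any(t: float, meal_times: Sequence[float],
                          mtime1: float, mtime2: float) -> int:
    """Indicator over possibly several meals; the window restarts per meal."""
    for mt in meal_times:
        if mt + mtime1 <= t < mt + mtime2:
            return 1
    return 0


def ode_rhs(
    state: Sequence[float],
    t: float,
    params: ModelParameters,
    schedule: EventSchedule,
    realization: RandomEffects = RandomEffects(),
) -> np.ndarray:
    """Time derivative of the five-state vector (pure function, no events)."""
    x1, x2, x3, x4, x5 = state
    ind = _window_indicator_any(
        t, schedule.fed_meal_times(), params.mtime1, params.mtime2
    )
    kg = effective_kg(params.tv_kg, params.e_food, ind) * math.exp(realization.eta_kg)
    kgp = params.kg_prime * math.exp(realization.eta_kg)  # shared IIV with kg
    kma = effective_kma(params.k_ma, params.e_bile, max(x5, 0.0))
    kel = params.k_el * math.exp(realization.eta_kel + realization.kappa_kel)
    return np.array([
        -kg * x1,
        kg * x1 - kma * x2,
        kma * x2 - kel * x3,
        -kgp * x4,
        kgp * x4 - params.k_out * x5,
    ])


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationProfile:
    """Solved trajectory on a time grid.

    ``states`` has one row per grid time and columns (X1..X5);
    ``eliminated_drug``/``eliminated_calories`` are the cumulative amounts
    removed by elimination, so mass balance can be verified exactly.
    """

    t: np.ndarray
    conc: np.ndarray               # ug/mL
    states: np.ndarray             # (n, 5)
    eliminated_drug: np.ndarray
    eliminated_calories: np.ndarray
    vc_eff: float

    def state_at(self, time: float) -> StateVector:
        i = int(np.searchsorted(self.t, time))
        if i >= len(self.t) or not math.isclose(self.t[i], time, abs_tol=1e-12):
            raise ValueError(f"time {time} not on the solution grid")
        return StateVector(*self.states[i])


def _breakpoints(schedule: EventSchedule, params: ModelParameters,
                 t_end: float) -> np.ndarray:
    pts = {0.0, t_end}
    for ev in schedule.dose_events:
        pts.add(ev.time)
    for ev in schedule.meal_events:
        pts.add(ev.time)
    for mt in schedule.fed_meal_times():
        for edge in (mt + params.mtime1, mt + params.mtime2):
            if 0.0 < edge < t_end:
                pts.add(edge)
    return np.array(sorted(p for p in pts if 0.0 <= p <= t_end))


def solve_profile(
    params: ModelParameters,
    schedule: EventSchedule,
    realization: RandomEffects = RandomEffects(),
    t_grid: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationProfile:
    """Integrate the model over ``t_grid`` with hard restarts at events.

    Dose amounts are added to X1 and meal calories (converted to
    calorie-units) to X4 at their event times.  Concentration is
    ``X3 / Vc_eff`` with the occasion-level food-type volume and the
    realization's ``eta_vc``/``kappa_vc`` applied.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 72.0, 289)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) < 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be sorted and non-negative")
    t_end = float(t_grid[-1])
    last_event = max([0.0, *[ev.time for ev in schedule.dose_events],
                      *[ev.time for ev in schedule.meal_events]])
    if t_end < last_event:
        raise ValueError("t_grid must cover all event times")

    kel = params.k_el * math.exp(realization.eta_kel + realization.kappa_kel)
    vc_eff = effective_vc(
        params.vc_over_f, schedule.food_type, params.e_vc1, params.e_vc2
    ) * math.exp(realization.eta_vc + realization.kappa_vc)
    cal_unit = params.calorie_unit_kcal

    dose_at = {}
    for ev in schedule.dose_events:
        dose_at[ev.time] = dose_at.get(ev.time, 0.0) + ev.amount
    meal_at = {}
    for ev in schedule.meal_events:
        meal_at[ev.time] = meal_at.get(ev.time, 0.0) + ev.calories / cal_unit

    # augmented state: X1..X5 + cumulative eliminated drug and calories
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        d = ode_rhs(y[:5], t, params, schedule, realization)
        return np.append(d, [kel * y[2], params.k_out * y[4]])

    breaks = _breakpoints(schedule, params, t_end)
    y = np.zeros(7)
    out = np.empty((len(t_grid), 7))
    if t_grid[0] == 0.0:
        pass  # filled after the bolus of the first segment below if any
    filled = np.zeros(len(t_grid), dtype=bool)

    for i in range(len(breaks)):
        t0 = breaks[i]
        y[0] += dose_at.get(t0, 0.0)
        y[3] += meal_at.get(t0, 0.0)
        t1 = breaks[i + 1] if i + 1 < len(breaks) else t_end
        # grid points in [t0, t1); the final breakpoint owns t_end
        if i + 1 < len(breaks):
            mask = (t_grid >= t0) & (t_grid < t1) & ~filled
        else:
            mask = (t_grid >= t0) & ~filled
        seg_times = t_grid[mask]
        if t1 > t0:
            sol = solve_ivp(
                rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol,
                dense_output=True,
            )
            if not sol.success:
                raise RuntimeError(
                    f"ODE solver failed on [{t0}, {t1}]: {sol.message}"
                )
            if len(seg_times):
                out[mask] = sol.sol(seg_times).T
                filled[mask] = True
            y = sol.y[:, -1]
        if len(seg_times) and t1 == t0:
            out[mask] = y
            filled[mask] = True
    # grid points exactly at t_end when t_end is the last breakpoint
    mask = ~filled
    if mask.any():
        out[mask] = y
        filled[mask] = True

    states = np.clip(out[:, :5], 0.0, None)
    conc = states[:, 2] / vc_eff
    return ConcentrationProfile(
        t=t_grid, conc=conc, states=states,
        eliminated_drug=out[:, 5], eliminated_calories=out[:, 6],
        vc_eff=vc_eff,
    )


# ---------------------------------------------------------------------------
# closed forms (independent cross-checks)
# ---------------------------------------------------------------------------

def bateman_cascade(
    t: np.ndarray | float, dose: float, kg: float, kma: float, kel: float,
    vc: float,
) -> np.ndarray:
    """Concentration for the constant-rate three-stage cascade (fasted case).

    Valid when the three rate constants are pairwise distinct; raises
    otherwise (the oracle is only used away from degeneracies).
    """
    t = np.asarray(t, dtype=float)
    a, b, c = kg, kma, kel
    if min(abs(a - b), abs(a - c), abs(b - c)) < 1e-10:
        raise ValueError("cascade closed form requires distinct rates")
    x3 = dose * a * b * (
        np.exp(-a * t) / ((b - a) * (c - a))
        + np.exp(-b * t) / ((a - b) * (c - b))
        + np.exp(-c * t) / ((a - c) * (b - c))
    )
    return x3 / vc


def calorie_profile(
    t: np.ndarray | float, cal_units: float, kg_prime: float, k_out: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (X4, X5) after a single meal at t=0.

    Uses the equal-rate limit ``kg' * X4_0 * t * exp(-kg' t)`` when the rate
    difference is below 1e-8 (the published kg' and k_out nearly coincide).
    """
    t = np.asarray(t, dtype=float)
    x4 = cal_units * np.exp(-kg_prime * t)
    if abs(k_out - kg_prime) < 1e-8:
        x5 = cal_units * kg_prime * t * np.exp(-kg_prime * t)
    else:
        x5 = cal_units * kg_prime * (
            np.exp(-kg_prime * t) - np.exp(-k_out * t)
        ) / (k_out - kg_prime)
    return x4, x5


# ---------------------------------------------------------------------------
# derived fed-state parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivedFedParameters:
    """Fed-state parameter values and their percent change from fasted.

    ``kma_fed`` is evaluated at the full meal calorie load expressed in
    calorie-units (the reporting convention); the dynamic simulation always
    uses the instantaneous X5(t).  ``bioavailability_fold`` reads the
    decrease in apparent volume as an increase in absorbed fraction,
    ``1 / (1 + e_vc)``.
    """

    food_type: FoodType
    meal_calories: float
    kg_fed: float
    kma_fed: float
    vc_fed: float
    bioavailability_fold: float
    kg_change_pct: float
    kma_change_pct: float
    vc_change_pct: float

    def as_dict(self) -> dict:
        return {
            "food_type": self.food_type.name,
            "meal_calories_kcal": self.meal_calories,
            "kg_fed_per_h": self.kg_fed,
            "kma_fed_per_h": self.kma_fed,
            "vc_fed_L": self.vc_fed,
            "bioavailability_fold": self.bioavailability_fold,
            "kg_change_pct": self.kg_change_pct,
            "kma_change_pct": self.kma_change_pct,
            "vc_change_pct": self.vc_change_pct,
        }


def derived_fed_parameters(
    params: ModelParameters, meal_calories: float, food_type: FoodType
) -> DerivedFedParameters:
    """Fed-state gastric emptying, absorption rate, volume and fold change."""
    food_type = FoodType(food_type)
    fed = food_type != FoodType.FASTED
    ind = 1 if fed else 0
    kg_fed = effective_kg(params.tv_kg, params.e_food, ind)
    x5 = (meal_calories / params.calorie_unit_kcal) if fed else 0.0
    kma_fed = effective_kma(params.k_ma, params.e_bile, x5)
    vc_fed = effective_vc(params.vc_over_f, food_type,
                          params.e_vc1, params.e_vc2)
    fold = params.vc_over_f / vc_fed
    return DerivedFedParameters(
        food_type=food_type,
        meal_calories=meal_calories if fed else 0.0,
        kg_fed=kg_fed,
        kma_fed=kma_fed,
        vc_fed=vc_fed,
        bioavailability_fold=fold,
        kg_change_pct=100.0 * (kg_fed / params.tv_kg - 1.0),
        kma_change_pct=100.0 * (kma_fed / params.k_ma - 1.0),
        vc_change_pct=100.0 * (vc_fed / params.vc_over_f - 1.0),
    )
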