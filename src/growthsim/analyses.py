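"""Applied computations built on the simulator.

Calibration of intake multipliers and individual height factors to observed
targets (scalar bisection against full simulations), generation of the
energy-intake series that tracks an arbitrary BMI-percentile curve (per-step
inversion of the energy balance), and the two energy-gap policy analyses:
the one-year weight-loss energy gap and the maintenance energy gap embedded
in an elevated population BMI curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .curves import DAYS_PER_YEAR, ReferenceCurveSet, Subject, biological_age
from .errors import CalibrationError, StarvationCollapse
from .simulator import (ModelParams, ReferenceIntake, Scenario, _Engine,
                        equilibrium_intake, reference_intake, reference_state,
                        simulate)


def scaled_reference_bmi(curves: ReferenceCurveSet, factor: float) -> Callable[[float], float]:
    """A BMI-for-age curve at a fixed multiple of the reference median — a
    convenient stand-in for a BMI percentile curve."""
    return lambda age_days: factor * curves.bmi_ref(age_days)


def shifted_reference_bmi(curves: ReferenceCurveSet,
                          excess: Callable[[float], float] | float) -> Callable[[float], float]:
    """Reference BMI plus an additive excess (constant or age-dependent,
    excess given per age in days)."""
    if callable(excess):
        return lambda age_days: curves.bmi_ref(age_days) + excess(age_days)
    return lambda age_days: curves.bmi_ref(age_days) + excess


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _final_bw(subject: Subject, curves: ReferenceCurveSet, scenario: Scenario,
              params: ModelParams) -> float:
    res = simulate(subject, curves, scenario, params)
    if res.collapsed:
        return 0.0  # far below any target; keeps the bisection one-sided
    return float(res.series["bw"][-1])


def calibrate_intake_multiplier(
        subject: Subject, curves: ReferenceCurveSet, target_weight: float,
        target_age_years: float, params: ModelParams | None = None,
        reference: ReferenceIntake | None = None,
        t_start: float = 0.0, bracket: tuple[float, float] = (0.4, 2.5),
        tol_kg: float = 0.05) -> float:
    """Fixed fractional change in reference intake reaching an observed
    weight-for-age; solved by bisection over whole-life simulations."""
    params = params or ModelParams()
    t_end = target_age_years * DAYS_PER_YEAR
    if reference is None:
        reference = reference_intake(subject, curves, params, t_start, t_end + 1)

    def f(mult: float) -> float:
        scn = Scenario.multiplier_of_reference(reference, [(t_start, t_end + 1, mult)],
                                               t_start, t_end)
        return _final_bw(subject, curves, scn, params) - target_weight

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"target {target_weight} kg not bracketed by multipliers {lo}-{hi} "
            f"(residuals {flo:.2f}, {fhi:.2f} kg)")
    mult = float(brentq(f, lo, hi, xtol=1e-5))
    resid = f(mult)
    if abs(resid) > tol_kg:
        raise CalibrationError(f"bisection residual {resid:.3f} kg exceeds {tol_kg} kg")
    return mult


def calibrate_height_factor(
        subject: Subject, curves: ReferenceCurveSet, observed_height: float,
        at_age_years: float, params: ModelParams | None = None,
        tol_m: float = 1e-3) -> float:
    """Individual height factor reproducing an observed height at an age
    under reference feeding."""
    if observed_height <= 0:
        raise CalibrationError("observed height must be positive")
    params = params or ModelParams()
    t_end = at_age_years * DAYS_PER_YEAR

    def height_at(factor: float) -> float:
        subj = Subject(**{**subject.__dict__, "height_factor": factor})
        scn = Scenario(0.0, t_end, None, 1.0)
        res = simulate(subj, curves, scn, params)
        if res.collapsed:
            return 0.0
        return float(res.series["h"][-1])

    bio = biological_age(t_end, subject)
    guess = observed_height / (curves.height_ref(bio) + curves.height_race_offset)
    lo, hi = 0.8 * guess, 1.25 * guess
    f = lambda x: height_at(x) - observed_height
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError("observed height not bracketed by factors "
                               f"{lo:.2f}-{hi:.2f}")
    factor = float(brentq(f, lo, hi, xtol=1e-5))
    if abs(f(factor)) > tol_m:
        raise CalibrationError("height calibration residual exceeds tolerance")
    return factor


# ---------------------------------------------------------------------------
# Percentile tracking
# ---------------------------------------------------------------------------

@dataclass
class TrackingResult:
    """EI series that makes simulated BMI track a target curve, with the
    resulting trajectories.  ``infeasible`` marks days where exact tracking
    would need negative intake (the stunting regime: EI clipped at zero)."""

    ages: np.ndarray
    ei: np.ndarray
    bmi: np.ndarray
    fm: np.ndarray
    ffm: np.ndarray
    h: np.ndarray
    infeasible: np.ndarray
    collapsed: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_days": self.ages, "ei": self.ei, "bmi": self.bmi,
            "fm": self.fm, "ffm": self.ffm, "h": self.h,
            "infeasible": self.infeasible,
        })


def percentile_tracking_intake(
        subject: Subject, curves: ReferenceCurveSet,
        bmi_percentile_curve: Callable[[float], float],
        params: ModelParams | None = None,
        t_start: float = 0.0, t_end: float = 20.0 * DAYS_PER_YEAR,
        dt: float = 1.0) -> TrackingResult:
    """Invert the energy balance day by day so that simulated BMI tracks the
    given BMI-for-age curve exactly (where feasible)."""
    params = params or ModelParams()
    eng = _Engine(subject, curves, params, t_start, t_end, dt)
    n = eng.n
    bio0 = subject.bioage_multiplier * t_start
    state = reference_state(subject, curves, t_start, params,
                            bmi=bmi_percentile_curve(bio0))
    fm, ffm, h = state.fm, state.ffm, state.h
    ages = eng.ages[: n + 1]
    out = {k: np.full(n + 1, np.nan) for k in ("ei", "bmi", "fm", "ffm", "h")}
    infeasible = np.zeros(n + 1, dtype=bool)
    collapsed = False
    ei_prev = 5.0
    last = n
    for i in range(n + 1):
        out["bmi"][i] = (fm + ffm) / (h * h)
        out["fm"][i], out["ffm"][i], out["h"][i] = fm, ffm, h
        if i == n:
            break
        target = bmi_percentile_curve(eng.bio[i + 1])

        def bmi_next(ei: float) -> float:
            f1, f2, h1, _ = eng.step(i, fm, ffm, h, ei)
            return (f1 + f2) / (h1 * h1)

        try:
            # Intake is under-determined by BMI alone while growth funding
            # modulates (BW and H^2 shrink together), so prefer the largest
            # intake consistent with the target: growth is sacrificed only
            # when the curve truly requires it (the stunting regime).
            ei_eq = eng.equilibrium_ei(i, fm, ffm, h)
            b_eq = bmi_next(ei_eq)
            if abs(b_eq - target) <= 2e-6 * target:
                ei = ei_eq
            elif b_eq < target:  # strictly increasing surplus regime
                hi = max(2.0 * ei_eq, 8.0)
                while bmi_next(hi) < target:
                    hi *= 2.0
                    if hi > 400.0:
                        raise CalibrationError("tracking intake diverged")
                ei = float(brentq(lambda x: bmi_next(x) - target, ei_eq, hi,
                                  xtol=1e-6))
            elif bmi_next(0.0) >= target:
                ei = 0.0
                infeasible[i] = True
            else:  # rightmost intake with bmi_next <= target
                lo, hi = 0.0, ei_eq
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    if bmi_next(mid) > target:
                        hi = mid
                    else:
                        lo = mid
                    if hi - lo < 1e-6:
                        break
                ei = lo
            fm, ffm, h, _ = eng.step(i, fm, ffm, h, ei)
        except StarvationCollapse:
            collapsed, last = True, i
            break
        out["ei"][i] = ei
        ei_prev = max(ei, 1.0)
    sl = slice(0, last + 1)
    return TrackingResult(ages=ages[sl], ei=out["ei"][sl], bmi=out["bmi"][sl],
                          fm=out["fm"][sl], ffm=out["ffm"][sl], h=out["h"][sl],
                          infeasible=infeasible[sl], collapsed=collapsed)


# ---------------------------------------------------------------------------
# Energy-gap analyses
# ---------------------------------------------------------------------------

def _bmi_after(subject: Subject, curves: ReferenceCurveSet, state,
               ei: float, horizon: float, params: ModelParams) -> float:
    """Final BMI under a constant intake; NaN if the simulation collapsed."""
    scn = Scenario.constant(ei, state.age, state.age + horizon,
                            initial_state=state)
    res = simulate(subject, curves, scn, params)
    if res.collapsed:
        return float("nan")
    return float(res.series["bmi"][-1])


def _solve_constant_ei(subject, curves, state, target_bmi, horizon, params) -> float:
    """Constant intake reaching ``target_bmi`` at the horizon.

    Collapsed runs below the equilibrium intake are treated as far-below
    target (starvation), above it as far-above (runaway growth), so the
    bracket stays sign-correct at the edges of the feasible window.
    """
    eq = equilibrium_intake(state, subject, curves, params)

    def f(ei: float) -> float:
        v = _bmi_after(subject, curves, state, ei, horizon, params) - target_bmi
        if v != v:  # collapsed
            return -1e3 if ei < eq else 1e3
        return v

    lo, hi = 0.0, 2.0 * eq
    if f(lo) > 0:
        raise CalibrationError("target BMI below what zero intake reaches")
    for _ in range(60):
        if f(hi) >= 0:
            break
        hi *= 1.4
    else:
        raise CalibrationError("constant-intake target BMI not bracketed")
    return float(brentq(f, lo, hi, xtol=1e-4))


def weight_loss_energy_gap(
        subject: Subject, curves: ReferenceCurveSet, delta_bmi: float,
        age_years: float, params: ModelParams | None = None,
        horizon: float = 365.0) -> tuple[float, float]:
    """Average daily energy gap for returning from ``delta_bmi`` above the
    reference BMI-for-age to the reference BMI over ``horizon`` days.

    Returns (absolute gap MJ/day, gap as a fraction of the maintenance
    intake at the elevated BMI).  Both legs are constant-intake solves: (a)
    the intake keeping the subject at the elevated BMI status and (b) the
    intake reaching the reference BMI at exactly the horizon.
    """
    if delta_bmi <= 0:
        raise CalibrationError("delta_bmi must be positive")
    params = params or ModelParams()
    age0 = age_years * DAYS_PER_YEAR
    bio_end = subject.bioage_multiplier * (age0 + horizon)
    bmi_ref_end = subject.bmi_factor * curves.bmi_ref(bio_end)
    state = reference_state(subject, curves, age0, params,
                            bmi=subject.bmi_factor
                            * curves.bmi_ref(subject.bioage_multiplier * age0)
                            + delta_bmi)
    ei_keep = _solve_constant_ei(subject, curves, state,
                                 bmi_ref_end + delta_bmi, horizon, params)
    ei_lose = _solve_constant_ei(subject, curves, state,
                                 bmi_ref_end, horizon, params)
    gap = ei_keep - ei_lose
    return gap, gap / ei_keep


@dataclass
class EnergyGapReport:
    """Per-age maintenance energy surplus embedded in an elevated BMI curve."""

    age_grid: np.ndarray          # years
    absolute_gap: np.ndarray      # MJ/day
    fractional_gap: np.ndarray    # fraction of the actual-BMI intake
    ei_actual: np.ndarray
    ei_reference: np.ndarray
    sex: str
    race: str

    @property
    def mean_absolute(self) -> float:
        return float(np.mean(self.absolute_gap))

    @property
    def mean_fractional(self) -> float:
        return float(np.mean(self.fractional_gap))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_years": self.age_grid, "absolute_gap": self.absolute_gap,
            "fractional_gap": self.fractional_gap, "ei_actual": self.ei_actual,
            "ei_reference": self.ei_reference,
        })


def maintenance_energy_gap(
        subject: Subject, curves: ReferenceCurveSet,
        actual_bmi_curve: Callable[[float], float],
        params: ModelParams | None = None,
        age_grid_years: Sequence[float] | None = None) -> EnergyGapReport:
    """Energy surplus needed to maintain an observed (elevated) BMI-for-age
    curve relative to maintaining the reference curve, per age."""
    params = params or ModelParams()
    if age_grid_years is None:
        age_grid_years = np.arange(3.0, 81.0, 1.0)
    ages = np.asarray(list(age_grid_years), dtype=float)
    gap = np.empty_like(ages)
    ei_act = np.empty_like(ages)
    ei_ref = np.empty_like(ages)
    for j, yr in enumerate(ages):
        age_days = yr * DAYS_PER_YEAR
        bio = subject.bioage_multiplier * age_days
        st_act = reference_state(subject, curves, age_days, params,
                                 bmi=actual_bmi_curve(bio))
        st_ref = reference_state(subject, curves, age_days, params)
        ei_act[j] = equilibrium_intake(st_act, subject, curves, params)
        ei_ref[j] = equilibrium_intake(st_ref, subject, curves, params)
        gap[j] = ei_act[j] - ei_ref[j]
    return EnergyGapReport(age_grid=ages, absolute_gap=gap,
                           fractional_gap=gap / ei_act, ei_actual=ei_act,
                           ei_reference=ei_ref, sex=subject.sex, race=subject.race)
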