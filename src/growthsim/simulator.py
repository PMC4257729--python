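"""Daily explicit-Euler integration of the three body states (FM, FFM, H).

Each step: map calendar to biological age, evaluate the canalized reference
curves, form the indicated state (BMI*, BW*, FM*, FFM*), compute the desired
height velocity (gap-closing, capped at four times the age-specific
reference rate, throttled below 85% of BMI-for-age), itemize the energy
budget, exchange FM/FFM toward the composition indicated by the current BMI,
resolve the supply/demand priority ladder, and advance the states by the
resolved net flows.  Realized height growth is the desired velocity scaled
by the fraction of the growth energy demand actually funded.

The core is fully deterministic; there is no randomness anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import allocation as alloc_mod
from . import composition as comp_mod
from .allocation import classify_stores, composition_correction
from .composition import CompositionParams, IndicatedState, body_energy
from .curves import (DAYS_PER_YEAR, ReferenceCurveSet, Subject, biological_age,
                     indicated_height)
from .demand import EnergyBudget, MetabolicParams
from .errors import CalibrationError, ParameterError, StarvationCollapse

_EPS = 1e-12


@dataclass(frozen=True)
class BodyState:
    """The three model states plus age."""

    fm: float    # kg
    ffm: float   # kg
    h: float     # m
    age: float   # days

    def __post_init__(self):
        if self.fm <= 0 or self.ffm <= 0 or self.h <= 0 or self.age < 0:
            raise ParameterError("body state requires positive masses/height and age >= 0")

    @property
    def bw(self) -> float:
        return self.fm + self.ffm

    @property
    def bmi(self) -> float:
        return self.bw / (self.h * self.h)

    @property
    def fat_fraction(self) -> float:
        return self.fm / self.bw


@dataclass(frozen=True)
class SimParams:
    """Dynamic/integration parameters.

    tau_height       days; gap-closing time constant for height canalization.
    tau_mass_gap     days; catch-up time constant pulling FM/FFM to trajectory.
    tau_correction   days; FM<->FFM composition-correction time constant.
    catchup_cap      total desired height velocity is capped at this multiple
                     of the age-specific reference velocity.
    cap_total        cap applies to the total velocity (else to the catch-up
                     increment only).
    stunting_threshold / stunting_floor
                     height growth is unthrottled at/above threshold x
                     BMI-for-age and fully suppressed at/below floor x, with
                     a linear ramp between.
    starvation_fraction
                     essential FM or FFM below this fraction of indicated
                     raises starvation collapse.
    dt               integration step, days (explicit Euler).
    """

    dt: float = 1.0
    tau_height: float = 180.0
    tau_mass_gap: float = 60.0
    tau_correction: float = 60.0
    catchup_cap: float = 4.0
    cap_total: bool = True
    stunting_threshold: float = 0.85
    stunting_floor: float = 0.60
    starvation_fraction: float = 0.20

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        for name in ("tau_height", "tau_mass_gap", "tau_correction"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.catchup_cap < 1:
            raise ParameterError("catchup_cap must be >= 1")
        if not 0 < self.stunting_floor < self.stunting_threshold <= 1:
            raise ParameterError("need 0 < stunting_floor < stunting_threshold <= 1")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all tunable parameter blocks."""

    composition: CompositionParams = field(default_factory=CompositionParams)
    metabolic: MetabolicParams = field(default_factory=MetabolicParams)
    sim: SimParams = field(default_factory=SimParams)


def stunting_factor(bmi: float, bmi_ref: float, threshold: float = 0.85,
                    floor: float = 0.60) -> float:
    """Throttle on height growth when BMI falls below the 85% of BMI-for-age
    threshold; linear ramp down to zero at the floor ratio."""
    if bmi <= 0 or bmi_ref <= 0:
        raise ParameterError("BMI inputs must be positive")
    r = bmi / bmi_ref
    if r >= threshold:
        return 1.0
    if r <= floor:
        return 0.0
    return (r - floor) / (threshold - floor)


def desired_height_velocity(h: float, h_star: float, v_ref: float,
                            gap_time_constant: float, cap: float = 4.0,
                            cap_total: bool = True) -> float:
    """Desired height velocity: reference rate plus gap closing, capped at
    ``cap`` times the age-specific reference rate (so zero for adults)."""
    if v_ref < 0:
        raise ParameterError("reference velocity must be non-negative")
    catchup = max(0.0, h_star - h) / gap_time_constant
    if cap_total:
        return max(0.0, min(v_ref + catchup, cap * v_ref))
    return max(0.0, v_ref + min(catchup, (cap - 1.0) * v_ref))


# ---------------------------------------------------------------------------
# Scenario / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceIntake:
    """Daily reference (on-trajectory) energy intake series, MJ/day."""

    ages: np.ndarray
    ei: np.ndarray

    def __call__(self, age_days: float) -> float:
        if age_days < self.ages[0] - 1e-9 or age_days > self.ages[-1] + 1e-9:
            raise ParameterError(
                f"age {age_days:.0f} d outside reference-intake span "
                f"[{self.ages[0]:.0f}, {self.ages[-1]:.0f}]")
        return float(np.interp(age_days, self.ages, self.ei))


@dataclass(frozen=True)
class Scenario:
    """An intake schedule over a time window.

    ``ei_schedule`` maps age (days) to intake (MJ/day).  ``initial_state``
    None means "reference individual at t_start" (on-trajectory composition
    and height).
    """

    t_start: float
    t_end: float
    ei_schedule: Callable[[float], float]
    dt: float = 1.0
    initial_state: BodyState | None = None
    label: str = ""

    def __post_init__(self):
        if self.t_end <= self.t_start or self.dt <= 0:
            raise ParameterError("need t_end > t_start and dt > 0")

    @staticmethod
    def constant(ei: float, t_start: float, t_end: float, dt: float = 1.0,
                 initial_state: BodyState | None = None, label: str = "") -> "Scenario":
        return Scenario(t_start, t_end, lambda age: ei, dt, initial_state, label)

    @staticmethod
    def piecewise(default: float | Callable[[float], float],
                  segments: Sequence[tuple[float, float, float]],
                  t_start: float, t_end: float, dt: float = 1.0,
                  initial_state: BodyState | None = None, label: str = "") -> "Scenario":
        """Absolute-intake segments ``(from_day, to_day, MJ/day)`` override the default."""
        base = default if callable(default) else (lambda age, v=default: v)

        def schedule(age: float) -> float:
            for t0, t1, v in segments:
                if t0 <= age < t1:
                    return v
            return base(age)

        return Scenario(t_start, t_end, schedule, dt, initial_state, label)

    @staticmethod
    def multiplier_of_reference(
            reference: ReferenceIntake,
            segments: Sequence[tuple[float, float, float]],
            t_start: float, t_end: float, dt: float = 1.0,
            initial_state: BodyState | None = None, label: str = "") -> "Scenario":
        """Multiplier segments ``(from_day, to_day, multiplier)`` on the
        reference intake; multiplier 1 elsewhere."""

        def schedule(age: float) -> float:
            m = 1.0
            for t0, t1, v in segments:
                if t0 <= age < t1:
                    m = v
                    break
            return m * reference(age)

        return Scenario(t_start, t_end, schedule, dt, initial_state, label)


_SERIES_FLOW = ("ei", "bmr", "pa", "tef", "at", "turnover", "growth_fm_demand",
                "growth_ffm_demand", "growth_fraction", "v_height", "stunting",
                "losses", "catabolized", "stored", "expended", "net_dfm",
                "net_dffm", "extra_fm", "extra_ffm")
_SERIES_STATE = ("age", "fm", "ffm", "h", "bw", "bmi", "fat_fraction",
                 "bmi_star", "bw_star", "fm_star", "ffm_star")


@dataclass
class SimResult:
    """Daily series of states, indicated states and resolved budgets.

    State columns have length n_steps + 1; flow columns describe the step
    *starting* at each row (NaN in the final row).
    """

    series: dict[str, np.ndarray]
    params: ModelParams
    collapsed: bool = False
    collapse_age: float | None = None
    label: str = ""

    def __getattr__(self, name):
        try:
            return self.series[name]
        except KeyError:
            raise AttributeError(name) from None

    @property
    def n_steps(self) -> int:
        return len(self.series["age"]) - 1

    def final_state(self) -> BodyState:
        s = self.series
        return BodyState(fm=s["fm"][-1], ffm=s["ffm"][-1], h=s["h"][-1], age=s["age"][-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.series)

    def energy_audit(self) -> tuple[float, float, float]:
        """(intake - expenditure, body-energy change, relative error).

        Whole-run first-law check: cumulative intake minus cumulative
        expenditure (maintenance components plus deposition losses) must
        equal the change in metabolizable body energy.
        """
        s = self.series
        dt = np.diff(s["age"])
        lhs = float(np.sum((s["ei"][:-1] - s["expended"][:-1]) * dt))
        comp = self.params.composition
        rhs = (body_energy(s["fm"][-1], s["ffm"][-1], comp)
               - body_energy(s["fm"][0], s["ffm"][0], comp))
        scale = max(1.0, float(np.sum(s["ei"][:-1] * dt)))
        return lhs, rhs, abs(lhs - rhs) / scale


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _Engine:
    """Precomputes reference-curve values on the integration grid and runs
    the per-step core on plain floats."""

    def __init__(self, subject: Subject, curves: ReferenceCurveSet,
                 params: ModelParams, t_start: float, t_end: float, dt: float):
        self.subject = subject
        self.curves = curves
        self.params = params
        self.dt = dt
        n = int(round((t_end - t_start) / dt))
        if n < 1:
            raise ParameterError("scenario shorter than one step")
        self.n = n
        ages = t_start + dt * np.arange(n + 2)  # one extra point for "next" lookups
        self.ages = ages
        bio = subject.bioage_multiplier * ages
        self.bio = bio
        c = curves
        self.href = c.height_ref(bio)
        self.dhref = c.height_ref.derivative(bio)
        self.bmiref = c.bmi_ref(bio)
        self.fmiref = c.fmi_ref(bio)
        self.paref = c.pa_ref(bio)
        self.cell = c.cellularity(bio)
        self.organ_fracs = np.vstack([curve(bio) for curve in c.organ_table.fraction_curves])
        self.organ_sigma = np.asarray(c.organ_table.specific_rates)
        met = params.metabolic
        self.organ_resp = np.array([
            met.organ_weight_response.get(name, 0.6) for name in c.organ_table.names
        ])
        comp = params.composition
        race_term = comp.race_terms.get(subject.race, 0.0)
        past_adult = np.maximum(0.0, bio / DAYS_PER_YEAR - comp.adult_age_years)
        self.anchor = (self.fmiref + race_term + subject.fmi_offset
                       + comp.age_slope * past_adult)
        self.h_star_arr = subject.height_factor * (self.href + c.height_race_offset)
        self.bmi_ref_adj = subject.bmi_factor * self.bmiref
        self.bw_ref_arr = self.bmi_ref_adj * self.h_star_arr ** 2
        self.v_ref_arr = (subject.height_factor * self.dhref
                          * subject.bioage_multiplier)

    # -- scalar helpers ----------------------------------------------------

    def _indicated(self, i: int, bmi: float, h: float) -> IndicatedState:
        comp = self.params.composition
        lam = comp.lambda_bmi
        bmi_star = lam * bmi + (1.0 - lam) * self.bmi_ref_adj[i]
        fmi_star = self.anchor[i] * (bmi_star / self.bmiref[i]) ** comp.gamma
        h2 = h * h
        return IndicatedState(bmi_star=bmi_star, bw_star=bmi_star * h2,
                              fmi_star=fmi_star, fm_star=fmi_star * h2,
                              ffm_star=(bmi_star - fmi_star) * h2)

    def _bmr(self, i: int, fm: float, ffm: float, bw_star: float) -> float:
        met = self.params.metabolic
        bw = fm + ffm
        deviation = (bw - bw_star) / bw_star
        masses = self.organ_fracs[:, i] * bw_star * (1.0 + self.organ_resp * deviation)
        np.maximum(masses, 0.0, out=masses)
        organ_mass = float(masses.sum())
        residual = ffm - organ_mass
        if residual < 0:
            raise StarvationCollapse(
                f"organ masses exceed FFM at age {self.ages[i]:.0f} d",
                age_days=float(self.ages[i]))
        res_cell = self.cell[i] if met.cellularity_applies_to_residual else 1.0
        return (float(masses @ self.organ_sigma) * self.cell[i]
                + met.sigma_fm * fm + met.sigma_residual * residual * res_cell)

    def _pa(self, i: int, bw: float) -> float:
        pa = self.subject.pa_factor * self.paref[i]
        if self.params.metabolic.pa_scales_with_weight:
            pa *= bw / self.bw_ref_arr[i]
        return pa

    def _demand_parts(self, i: int, fm: float, ffm: float, h: float):
        """Everything that does not depend on EI."""
        p = self.params
        comp, met, sim = p.composition, p.metabolic, p.sim
        bw = fm + ffm
        bmi = bw / (h * h)
        ind = self._indicated(i, bmi, h)
        # height velocity
        v_ref = max(0.0, self.v_ref_arr[i])
        stunt = stunting_factor(bmi, self.bmi_ref_adj[i],
                                sim.stunting_threshold, sim.stunting_floor)
        v_des = desired_height_velocity(h, self.h_star_arr[i], v_ref,
                                        sim.tau_height, sim.catchup_cap,
                                        sim.cap_total) * stunt
        # indicated trajectory one step ahead: the indicated BMI advances by
        # the full reference-curve increment (constant offset from the
        # canalized curve), and height by the desired velocity
        h_next = h + v_des * self.dt
        bmi_star_n = ind.bmi_star + (self.bmi_ref_adj[i + 1] - self.bmi_ref_adj[i])
        fmi_star_n = self.anchor[i + 1] * (bmi_star_n / self.bmiref[i + 1]) ** comp.gamma
        h2n = h_next * h_next
        fm_star_n = fmi_star_n * h2n
        ffm_star_n = (bmi_star_n - fmi_star_n) * h2n
        v_fm_motion = (fm_star_n - ind.fm_star) / self.dt
        v_ffm_motion = (ffm_star_n - ind.ffm_star) / self.dt
        v_fm_gap = max(0.0, ind.fm_star - fm) / sim.tau_mass_gap
        v_ffm_gap = max(0.0, ind.ffm_star - ffm) / sim.tau_mass_gap
        v_fm = v_fm_motion + v_fm_gap
        v_ffm = v_ffm_motion + v_ffm_gap
        rho_fm_dep = comp.rho_fm / met.deposition_efficiency_fm
        rho_ffm_dep = (comp_mod.ffm_energy_density(ffm, comp)
                       / met.deposition_efficiency_ffm)
        g_fm = max(0.0, v_fm) * rho_fm_dep
        g_ffm = max(0.0, v_ffm) * rho_ffm_dep
        # trajectory-motion share of the demand: funded first; its funding
        # fraction is what throttles height growth under scarcity
        g_motion = (max(0.0, v_fm_motion) * rho_fm_dep
                    + max(0.0, v_ffm_motion) * rho_ffm_dep)
        turnover = met.turnover_rate * bw
        # a falling indicated trajectory sheds mass; the released energy
        # enters the ladder as supply (trajectory involution credit)
        shed_fm = shed_ffm = 0.0
        if v_fm < 0.0:
            shed_fm = min(-v_fm * self.dt, max(0.0, fm - fm_star_n))
        if v_ffm < 0.0:
            shed_ffm = min(-v_ffm * self.dt, max(0.0, ffm - ffm_star_n))
        shed_credit = (shed_fm * comp.rho_fm
                       + comp_mod.ffm_energy_delta(ffm - shed_ffm, ffm, comp))
        # composition correction toward the FMI indicated by the *current* BMI
        fm_ind_cur = self.anchor[i] * (bmi / self.bmiref[i]) ** comp.gamma * h * h
        corr = composition_correction(fm, ffm, fm_ind_cur, sim.tau_correction,
                                      self.dt, comp, met)
        bmr = self._bmr(i, fm, ffm, ind.bw_star)
        pa = self._pa(i, bw)
        p_ffm = 1.0 - comp.gamma * (fm_ind_cur / (h * h)) / bmi
        p_ffm = min(0.99, max(0.01, p_ffm))
        return (ind, bmi, v_des, stunt, g_fm, g_ffm, g_motion, turnover, corr,
                bmr, pa, p_ffm, shed_fm, shed_ffm, shed_credit)

    def equilibrium_ei(self, i: int, fm: float, ffm: float, h: float) -> float:
        """Intake at which deviation flows vanish (demand-matching intake)."""
        p = self.params
        met = p.metabolic
        (ind, bmi, v_des, stunt, g_fm, g_ffm, g_motion, turnover, corr, bmr,
         pa, p_ffm, shed_fm, shed_ffm, shed_credit) = self._demand_parts(i, fm, ffm, h)
        g = g_fm + g_ffm
        corr_d = corr.demand_energy / self.dt
        corr_s = (corr.supply_energy + shed_credit) / self.dt

        def f(ei: float) -> float:
            tef_e = met.tef_fraction * ei
            pre_at = bmr + pa + tef_e + turnover + corr_d
            if met.at_includes_growth:
                pre_at += g
            at = met.at_coefficient * (ei / pre_at - 1.0) * bmr
            return ei + corr_s - (bmr + pa + tef_e + turnover + at + corr_d + g)

        guess = (bmr + pa + turnover + g + corr_d - corr_s) / (1.0 - met.tef_fraction)
        if abs(f(guess)) < 1e-10:
            return guess
        lo, hi = 1e-3, max(60.0, 2.0 * guess)
        if f(lo) > 0 or f(hi) < 0:
            raise CalibrationError("no bracketing interval for equilibrium intake")
        return float(brentq(f, lo, hi, xtol=1e-10))

    def step(self, i: int, fm: float, ffm: float, h: float, ei: float):
        """Advance one step; returns (fm1, ffm1, h1, record)."""
        p = self.params
        comp, met, sim = p.composition, p.metabolic, p.sim
        dt = self.dt
        (ind, bmi, v_des, stunt, g_fm, g_ffm, g_motion, turnover, corr, bmr,
         pa, p_ffm, shed_fm, shed_ffm, shed_credit) = self._demand_parts(i, fm, ffm, h)
        tef_e = met.tef_fraction * ei
        corr_d = corr.demand_energy / dt
        corr_s = (corr.supply_energy + shed_credit) / dt
        pre_at = bmr + pa + tef_e + turnover + corr_d
        if met.at_includes_growth:
            pre_at += g_fm + g_ffm
        at = met.at_coefficient * (ei / pre_at - 1.0) * bmr
        maintenance = bmr + pa + tef_e + turnover + at + corr_d
        # apply the correction exchange and trajectory shedding, then the ladder
        fm_c = fm + corr.dfm - shed_fm
        ffm_c = ffm + corr.dffm - shed_ffm
        stores = classify_stores(fm_c, ffm_c, ind)
        res = alloc_mod.allocate(
            ei=(ei + corr_s) * dt, maintenance=maintenance * dt,
            growth_fm=g_fm * dt, growth_ffm=g_ffm * dt,
            stores=stores, p_ffm=p_ffm, fm=fm_c, ffm=ffm_c,
            comp=comp, met=met)
        if res.unmet_maintenance > 1e-9:
            raise StarvationCollapse(
                f"maintenance unmet by {res.unmet_maintenance:.3f} MJ at age "
                f"{self.ages[i]:.0f} d", age_days=float(self.ages[i]))
        fm1 = fm_c + res.net_dfm
        ffm1 = ffm_c + res.net_dffm
        # the trajectory-motion share of growth demand is funded first; its
        # funding fraction throttles height growth
        funded = res.growth_fm_funded + res.growth_ffm_funded
        if g_motion * dt > 1e-12:
            frac = min(1.0, funded / (g_motion * dt))
        else:
            frac = 1.0
        v_real = v_des * frac
        h1 = h + v_real * dt
        if (min(fm1, ind.fm_star) < sim.starvation_fraction * ind.fm_star
                or min(ffm1, ind.ffm_star) < sim.starvation_fraction * ind.ffm_star):
            raise StarvationCollapse(
                f"essential stores below {sim.starvation_fraction:.0%} of indicated "
                f"at age {self.ages[i]:.0f} d", age_days=float(self.ages[i]))
        losses = (res.deposition_losses + corr.losses) / dt
        catabolized = (res.catabolized_energy + corr.released_energy + shed_credit) / dt
        stored = (res.stored_energy + corr.stored_energy) / dt
        expended = bmr + pa + tef_e + turnover + at + losses
        record = dict(
            ei=ei, bmr=bmr, pa=pa, tef=tef_e, at=at, turnover=turnover,
            growth_fm_demand=g_fm, growth_ffm_demand=g_ffm, growth_fraction=frac,
            v_height=v_real, stunting=stunt, losses=losses,
            catabolized=catabolized, stored=stored, expended=expended,
            net_dfm=(fm1 - fm) / dt, net_dffm=(ffm1 - ffm) / dt,
            extra_fm=stores.extra_fm, extra_ffm=stores.extra_ffm,
            bmi_star=ind.bmi_star, bw_star=ind.bw_star,
            fm_star=ind.fm_star, ffm_star=ind.ffm_star,
        )
        return fm1, ffm1, h1, record


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def reference_state(subject: Subject, curves: ReferenceCurveSet, age_days: float,
                    params: ModelParams | None = None,
                    bmi: float | None = None) -> BodyState:
    """On-trajectory body state at an age: reference height and, by default,
    reference BMI with composition at the indicated FMI."""
    params = params or ModelParams()
    comp = params.composition
    bio = biological_age(age_days, subject)
    h = indicated_height(curves, subject, bio)
    if bmi is None:
        bmi = subject.bmi_factor * curves.bmi_ref(bio)
    fmi = comp_mod.indicated_fmi(bmi, curves.bmi_ref(bio), curves.fmi_ref(bio),
                                 subject, bio, comp)
    fm = fmi * h * h
    return BodyState(fm=fm, ffm=bmi * h * h - fm, h=h, age=age_days)


def step(state: BodyState, subject: Subject, curves: ReferenceCurveSet,
         ei: float, params: ModelParams | None = None,
         dt: float | None = None) -> BodyState:
    """Advance a single explicit-Euler step of length dt (default from params)."""
    params = params or ModelParams()
    dt = dt if dt is not None else params.sim.dt
    if ei < 0:
        raise ParameterError("intake must be non-negative")
    eng = _Engine(subject, curves, params, state.age, state.age + dt, dt)
    fm1, ffm1, h1, _ = eng.step(0, state.fm, state.ffm, state.h, ei)
    return BodyState(fm=fm1, ffm=ffm1, h=h1, age=state.age + dt)


def equilibrium_intake(state: BodyState, subject: Subject,
                       curves: ReferenceCurveSet,
                       params: ModelParams | None = None) -> float:
    """Intake (MJ/day) at which the state shows no deviation flows: no store
    catabolism, no extra deposition, and growth demand exactly funded.  For a
    growing child this is the reference intake (it covers growth)."""
    params = params or ModelParams()
    eng = _Engine(subject, curves, params, state.age, state.age + params.sim.dt,
                  params.sim.dt)
    return eng.equilibrium_ei(0, state.fm, state.ffm, state.h)


def simulate(subject: Subject, curves: ReferenceCurveSet, scenario: Scenario,
             params: ModelParams | None = None) -> SimResult:
    """Integrate a scenario; on starvation collapse the partial series is
    returned with the collapse flag set."""
    params = params or ModelParams()
    eng = _Engine(subject, curves, params, scenario.t_start, scenario.t_end,
                  scenario.dt)
    n = eng.n
    state = scenario.initial_state or reference_state(
        subject, curves, scenario.t_start, params)
    if abs(state.age - scenario.t_start) > 1e-6:
        raise ParameterError("initial state age must equal scenario t_start")
    cols = {k: np.full(n + 1, np.nan) for k in _SERIES_FLOW}
    cols.update({k: np.full(n + 1, np.nan) for k in _SERIES_STATE})
    fm, ffm, h = state.fm, state.ffm, state.h
    collapsed, collapse_age = False, None
    last = n
    for i in range(n + 1):
        cols["age"][i] = eng.ages[i]
        cols["fm"][i], cols["ffm"][i], cols["h"][i] = fm, ffm, h
        cols["bw"][i] = fm + ffm
        cols["bmi"][i] = (fm + ffm) / (h * h)
        cols["fat_fraction"][i] = fm / (fm + ffm)
        if i == n:
            break
        try:
            ei = (eng.equilibrium_ei(i, fm, ffm, h)
                  if scenario.ei_schedule is None
                  else max(0.0, scenario.ei_schedule(eng.ages[i])))
            fm, ffm, h, rec = eng.step(i, fm, ffm, h, ei)
        except StarvationCollapse as exc:
            collapsed, collapse_age, last = True, exc.age_days, i
            break
        for k, v in rec.items():
            cols[k][i] = v
        cols["bmi_star"][i] = rec["bmi_star"]
    if collapsed:
        cols = {k: v[: last + 1] for k, v in cols.items()}
    return SimResult(series=cols, params=params, collapsed=collapsed,
                     collapse_age=collapse_age, label=scenario.label)


def reference_intake(subject: Subject, curves: ReferenceCurveSet,
                     params: ModelParams | None = None,
                     t_start: float = 0.0,
                     t_end: float = 20.0 * DAYS_PER_YEAR,
                     dt: float = 1.0) -> ReferenceIntake:
    """Daily intake of the on-trajectory (reference) individual, obtained by
    feeding the demand-matching intake at every step."""
    params = params or ModelParams()
    scn = Scenario(t_start, t_end, None, dt, label="reference")
    result = simulate(subject, curves, scn, params)
    ri = ReferenceIntake(ages=result.series["age"][:-1].copy(),
                         ei=result.series["ei"][:-1].copy())
    object.__setattr__(ri, "sim", result)
    return ri
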