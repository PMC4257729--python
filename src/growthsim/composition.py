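"""Indicated body composition and body-energy accounting.

The central empirical relationship is the indicated fat-mass-index family
FMI*(BMI): for a given BMI, the most likely FMI is the age/sex/race
reference FMI (the "anchor") scaled by a power of the BMI deviation from
its reference,

    FMI*(BMI) = anchor * (BMI / BMI_ref)**gamma,
    anchor    = FMI_ref(bio_age) + race_term + fmi_offset + age_slope * years_past_adult.

Differentiating the identity FFM = (BMI - FMI) * H^2 at fixed height gives
the partition fraction — the share of a marginal body-weight change
deposited as (or drawn from) fat-free mass:

    p_FFM = 1 - dFMI*/dBMI = 1 - gamma * FMI*(BMI) / BMI.

The classical Forbes partition is provided for side-by-side comparison only.

Energy bookkeeping: fat mass has a constant metabolizable energy density
rho_FM; the marginal energy density of fat-free mass rises linearly with
FFM and saturates at the adult value (5 MJ/kg by default).  Deposition and
catabolism solvers below invert the exact piecewise-quadratic cumulative
energy curve so that whole-simulation energy audits close to machine
precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .curves import DAYS_PER_YEAR, ReferenceCurveSet, Subject
from .errors import CompositionError, ParameterError

logger = logging.getLogger(__name__)

#: default additive FMI adjustments by race (kg/m^2)
FMI_RACE_TERMS: dict[str, float] = {
    "nh_white": 0.0,
    "nh_black": -0.60,
    "mexican_american": 0.30,
    "other": 0.0,
}


@dataclass(frozen=True)
class CompositionParams:
    """Coefficients of the indicated-BMI/FMI equations and energy densities.

    lambda_bmi        weight on the *current* BMI in the indicated-BMI blend
                      (1 - lambda_bmi goes to the biological reference BMI).
    gamma             elasticity of FMI* with respect to BMI.
    race_terms        additive FMI anchor shifts (kg/m^2) by race.
    age_slope         additive post-adult FMI anchor slope (kg/m^2 per year);
                      default 0 because the bundled reference FMI curves
                      already carry the aging term.
    rho_fm            metabolizable energy density of fat mass, MJ/kg.
    rho_ffm_adult     saturated (adult) marginal energy density of FFM, MJ/kg.
    rho_ffm_intercept / rho_ffm_slope
                      marginal FFM density below saturation:
                      rho(FFM) = intercept + slope * FFM, continuous at the
                      saturation point (rho_ffm_adult - intercept) / slope kg.
    """

    lambda_bmi: float = 0.5
    gamma: float = 2.0
    race_terms: dict[str, float] = field(default_factory=lambda: dict(FMI_RACE_TERMS))
    age_slope: float = 0.0
    adult_age_years: float = 20.0
    rho_fm: float = 39.5
    rho_ffm_adult: float = 5.0
    rho_ffm_intercept: float = 1.5
    rho_ffm_slope: float = 0.0875

    def __post_init__(self):
        if not 0.0 <= self.lambda_bmi <= 1.0:
            raise ParameterError("lambda_bmi must lie in [0, 1]")
        if self.gamma < 0:
            raise ParameterError("gamma must be non-negative")
        if not self.rho_fm > self.rho_ffm_adult > 0:
            raise ParameterError("need rho_fm > rho_ffm_adult > 0")
        if self.rho_ffm_intercept <= 0 or self.rho_ffm_intercept > self.rho_ffm_adult:
            raise ParameterError("rho_ffm_intercept must lie in (0, rho_ffm_adult]")
        if self.rho_ffm_slope < 0:
            raise ParameterError("rho_ffm_slope must be non-negative")

    @property
    def ffm_saturation(self) -> float:
        """FFM (kg) beyond which the marginal density is the adult constant."""
        if self.rho_ffm_slope == 0:
            return 0.0
        return (self.rho_ffm_adult - self.rho_ffm_intercept) / self.rho_ffm_slope


@dataclass(frozen=True)
class IndicatedState:
    """Trajectory targets at the current instant."""

    bmi_star: float  # kg/m^2
    bw_star: float   # kg
    fmi_star: float  # kg/m^2
    fm_star: float   # kg
    ffm_star: float  # kg

    def __post_init__(self):
        if min(self.bmi_star, self.bw_star, self.fmi_star, self.fm_star, self.ffm_star) <= 0:
            raise CompositionError("indicated state fields must all be positive")


def indicated_bmi(bmi_current: float, bmi_ref: float, subject: Subject,
                  params: CompositionParams) -> float:
    """Indicated BMI*: weighted sum of current and biological reference BMI.

    Height is tightly canalized but BMI only partially, so the trajectory
    target tracks the individual's current BMI with weight ``lambda_bmi``.
    """
    if bmi_current <= 0 or bmi_ref <= 0:
        raise ParameterError("BMI inputs must be positive")
    lam = params.lambda_bmi
    return lam * bmi_current + (1.0 - lam) * subject.bmi_factor * bmi_ref


def fmi_anchor(fmi_ref: float, subject: Subject, bio_age_days: float,
               params: CompositionParams) -> float:
    """Reference FMI adjusted for race, individual fat predisposition and age."""
    anchor = (fmi_ref + params.race_terms.get(subject.race, 0.0) + subject.fmi_offset)
    past_adult = max(0.0, bio_age_days / DAYS_PER_YEAR - params.adult_age_years)
    return anchor + params.age_slope * past_adult


def indicated_fmi(bmi: float, bmi_ref: float, fmi_ref: float, subject: Subject,
                  bio_age_days: float, params: CompositionParams) -> float:
    """Most likely FMI for the given BMI (power-law family, anchored at BMI_ref)."""
    if bmi <= 0 or bmi_ref <= 0 or fmi_ref <= 0:
        raise ParameterError("BMI/FMI inputs must be positive")
    anchor = fmi_anchor(fmi_ref, subject, bio_age_days, params)
    if anchor <= 0:
        raise CompositionError(f"FMI anchor {anchor:.3f} is not positive")
    fmi = anchor * (bmi / bmi_ref) ** params.gamma
    if fmi >= bmi:
        raise CompositionError(
            f"indicated FMI {fmi:.2f} >= BMI {bmi:.2f}: invalid coefficients"
        )
    return fmi


def partition_fraction(bmi: float, bmi_ref: float, fmi_ref: float, subject: Subject,
                       bio_age_days: float, params: CompositionParams) -> float:
    """Share of a marginal body-weight change deposited as fat-free mass.

    Analytic derivative of the power-law FMI family; clipped to [0.01, 0.99]
    with a logged warning at pathological BMIs so flows stay well defined in
    extreme starvation/overfeeding scenarios.
    """
    fmi = indicated_fmi(bmi, bmi_ref, fmi_ref, subject, bio_age_days, params)
    p = 1.0 - params.gamma * fmi / bmi
    if p < 0.01 or p > 0.99:
        logger.warning("partition fraction %.4f at BMI %.1f clipped to [0.01, 0.99]", p, bmi)
        p = min(0.99, max(0.01, p))
    return p


def split_indicated(bmi_star: float, h: float, bmi_ref: float, fmi_ref: float,
                    subject: Subject, bio_age_days: float,
                    params: CompositionParams) -> IndicatedState:
    """Partition the indicated body weight into indicated FM and FFM."""
    if h <= 0:
        raise ParameterError("height must be positive")
    fmi_star = indicated_fmi(bmi_star, bmi_ref, fmi_ref, subject, bio_age_days, params)
    bw_star = bmi_star * h * h
    fm_star = fmi_star * h * h
    return IndicatedState(bmi_star=bmi_star, bw_star=bw_star, fmi_star=fmi_star,
                          fm_star=fm_star, ffm_star=bw_star - fm_star)


def forbes_partition(bw: float, fm: float) -> float:
    """Classical Forbes fat-free share of a marginal weight change.

    Provided only for side-by-side comparison with the package's own
    partition; dFFM/dBW = 10.4 / (10.4 + FM).
    """
    if not 0.0 < fm < bw:
        raise ParameterError("need 0 < fm < bw")
    return 10.4 / (10.4 + fm)


# ---------------------------------------------------------------------------
# Body energy
# ---------------------------------------------------------------------------

def ffm_energy_density(ffm: float, params: CompositionParams) -> float:
    """Marginal metabolizable energy density of FFM (MJ/kg).

    Linear ramp from the intercept, saturating at the adult value; continuous
    at the junction.
    """
    if ffm < 0:
        raise ParameterError("ffm must be non-negative")
    return min(params.rho_ffm_adult,
               params.rho_ffm_intercept + params.rho_ffm_slope * ffm)


def ffm_energy(ffm: float, params: CompositionParams) -> float:
    """Cumulative metabolizable energy of the FFM compartment (MJ), the exact
    integral of the marginal density from zero."""
    if ffm < 0:
        raise ParameterError("ffm must be non-negative")
    fs = params.ffm_saturation
    c0, c1, ra = params.rho_ffm_intercept, params.rho_ffm_slope, params.rho_ffm_adult
    if ffm <= fs:
        return c0 * ffm + 0.5 * c1 * ffm * ffm
    e_sat = c0 * fs + 0.5 * c1 * fs * fs
    return e_sat + ra * (ffm - fs)


def body_energy(fm: float, ffm: float, params: CompositionParams) -> float:
    """Total metabolizable body energy (MJ): constant-density fat plus the
    integrated FFM energy curve.  Additive and zero at zero mass."""
    if fm < 0 or ffm < 0:
        raise ParameterError("masses must be non-negative")
    return params.rho_fm * fm + ffm_energy(ffm, params)


# ---------------------------------------------------------------------------
# Exact mass <-> energy solvers for the allocation step
# ---------------------------------------------------------------------------

def _pos_root(a: float, b: float, s: float) -> float:
    """Positive root of a*m^2 + b*m = s (b > 0, s >= 0), stable for small a."""
    if s <= 0.0:
        return 0.0
    disc = b * b + 4.0 * a * s
    if disc < 0.0:  # only possible for a < 0 past the vertex; caller caps first
        disc = 0.0
    return 2.0 * s / (b + math.sqrt(disc))


def solve_deposit(ffm0: float, p_ffm: float, energy: float,
                  eff_ffm: float, eff_fm: float, params: CompositionParams) -> float:
    """Total mass m deposited (p_ffm of it as FFM) by spending ``energy`` MJ.

    Inverts  E_ffm(ffm0 + p*m) - E_ffm(ffm0)) / eff_ffm
             + (1-p) * m * rho_fm / eff_fm  =  energy
    exactly across the saturation breakpoint of the FFM density curve.
    """
    if energy <= 0.0:
        return 0.0
    fs = params.ffm_saturation
    c0, c1, ra, rf = (params.rho_ffm_intercept, params.rho_ffm_slope,
                      params.rho_ffm_adult, params.rho_fm)
    k_fm = (1.0 - p_ffm) * rf / eff_fm
    m_total, f, s = 0.0, ffm0, energy
    if p_ffm <= 0.0:
        return s / k_fm
    if f < fs:
        a = 0.5 * c1 * p_ffm * p_ffm / eff_ffm
        b = (c0 + c1 * f) * p_ffm / eff_ffm + k_fm
        m = _pos_root(a, b, s)
        m_cap = (fs - f) / p_ffm
        if m <= m_cap:
            return m
        spent = a * m_cap * m_cap + b * m_cap
        m_total, f, s = m_cap, fs, s - spent
    k = p_ffm * ra / eff_ffm + k_fm
    return m_total + s / k


def solve_consume(ffm0: float, p_ffm: float, energy: float,
                  params: CompositionParams) -> float:
    """Total mass m catabolized (p_ffm of it FFM) to release ``energy`` MJ.

    Inverts  (E_ffm(ffm0) - E_ffm(ffm0 - p*m)) + (1-p) * m * rho_fm = energy.
    The caller is responsible for capping against available mass.
    """
    if energy <= 0.0:
        return 0.0
    fs = params.ffm_saturation
    c0, c1, ra, rf = (params.rho_ffm_intercept, params.rho_ffm_slope,
                      params.rho_ffm_adult, params.rho_fm)
    k_fm = (1.0 - p_ffm) * rf
    m_total, f, s = 0.0, ffm0, energy
    if p_ffm <= 0.0:
        return s / k_fm
    if f > fs:
        k = p_ffm * ra + k_fm
        m = s / k
        m_cap = (f - fs) / p_ffm
        if m <= m_cap:
            return m
        m_total, f, s = m_cap, fs, s - k * m_cap
    a = -0.5 * c1 * p_ffm * p_ffm
    b = (c0 + c1 * f) * p_ffm + k_fm
    return m_total + _pos_root(a, b, s)


def ffm_energy_delta(f0: float, f1: float, params: CompositionParams) -> float:
    """E_ffm(f1) - E_ffm(f0), exact."""
    return ffm_energy(f1, params) - ffm_energy(f0, params)
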