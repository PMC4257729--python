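"""Itemized daily energy demand.

Total demand is the sum of organ-based basal metabolism, physical activity,
the thermic effect of feeding, energy for deposition and turnover of tissue,
and a signed adaptive-thermogenesis adjustment driven by the gap between
intake and the other demand components:

    D = BMR + PA + TEF + growth_FM + growth_FFM + turnover + AT.

BMR sums the masses of the high-metabolic-rate organs (liver, brain, heart,
kidneys) times their specific rates, adjusted for age-dependent relative
cellularity, plus low-rate contributions from adipose tissue and the
residual fat-free mass.  Organ masses are tied to the *indicated* body
weight and respond partially when actual weight deviates from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import CompositionParams, IndicatedState, ffm_energy_density
from .curves import ReferenceCurveSet, Subject, reference_bmi, reference_pa
from .errors import CompositionError, ParameterError


@dataclass(frozen=True)
class MetabolicParams:
    """Metabolic-rate and efficiency parameters.

    tef_fraction            thermic effect of feeding as a fraction of intake.
    at_coefficient          strength of adaptive thermogenesis; the signed
                            adjustment is at_coefficient * (EI/D_pre - 1) * BMR,
                            applied to BMR only.
    at_includes_growth      whether catch-up/growth needs enter the demand
                            D_pre that drives adaptive thermogenesis.
    deposition_efficiency_* net efficiency of converting dietary energy into
                            stored tissue energy.
    organ_weight_response   per-organ slope of organ mass with relative
                            body-weight deviation from indicated weight.
    sigma_fm / sigma_residual
                            specific metabolic rates (MJ/kg/day) of adipose
                            tissue and of residual FFM (FFM minus the named
                            organs).
    turnover_rate           MJ per kg body weight per day for mass turnover;
                            zero by default (folded into the residual BMR).
    pa_scales_with_weight   scale the age-referenced activity energy by
                            BW / BW_ref(age): moving more mass costs
                            proportionally more energy.
    """

    tef_fraction: float = 0.10
    at_coefficient: float = 0.25
    at_includes_growth: bool = True
    deposition_efficiency_fm: float = 0.98
    deposition_efficiency_ffm: float = 0.85
    organ_weight_response: dict[str, float] = field(
        default_factory=lambda: {"brain": 0.0, "liver": 0.6, "heart": 0.6, "kidneys": 0.6}
    )
    sigma_fm: float = 0.0187
    sigma_residual: float = 0.10
    turnover_rate: float = 0.0
    pa_scales_with_weight: bool = True
    cellularity_applies_to_residual: bool = True
    bmr_ceiling: float = 30.0

    def __post_init__(self):
        if not 0.0 <= self.tef_fraction < 0.3:
            raise ParameterError("tef_fraction must lie in [0, 0.3)")
        if not 0.0 <= self.at_coefficient <= 1.0:
            raise ParameterError("at_coefficient must lie in [0, 1]")
        for name in ("deposition_efficiency_fm", "deposition_efficiency_ffm"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ParameterError(f"{name} must lie in (0, 1]")
        if self.sigma_fm < 0 or self.sigma_residual < 0 or self.turnover_rate < 0:
            raise ParameterError("specific rates must be non-negative")


@dataclass(frozen=True)
class EnergyBudget:
    """Itemized demand for one day (MJ/day); total is the exact sum of parts."""

    bmr: float
    pa: float
    tef: float
    growth_fm: float
    growth_ffm: float
    turnover: float
    at_adjustment: float

    @property
    def total(self) -> float:
        return (self.bmr + self.pa + self.tef + self.growth_fm
                + self.growth_ffm + self.turnover + self.at_adjustment)

    @property
    def maintenance(self) -> float:
        """Demand that must be met every day regardless of growth."""
        return self.bmr + self.pa + self.tef + self.turnover + self.at_adjustment

    def __post_init__(self):
        for name in ("bmr", "pa", "tef", "growth_fm", "growth_ffm", "turnover"):
            if getattr(self, name) < 0:
                raise ParameterError(f"budget component {name} must be non-negative")


def bmr_demand(fm: float, ffm: float, indicated: IndicatedState,
               curves: ReferenceCurveSet, bio_age_days: float,
               params: MetabolicParams) -> float:
    """Organ-based basal metabolic rate (MJ/day).

    Each organ's mass is its age-dependent fraction of the indicated body
    weight, scaled by the organ's response to the relative deviation of
    actual from indicated weight; specific rates are multiplied by the
    age-dependent relative cellularity.  Adipose tissue and the residual
    fat-free mass contribute at their (low) specific rates.
    """
    if fm < 0 or ffm <= 0:
        raise ParameterError("masses must be positive")
    table = curves.organ_table
    cell = curves.cellularity(bio_age_days)
    bw = fm + ffm
    deviation = (bw - indicated.bw_star) / indicated.bw_star
    organ_mass_total = 0.0
    organ_energy = 0.0
    for name, curve, sigma in zip(table.names, table.fraction_curves, table.specific_rates):
        response = params.organ_weight_response.get(name, 0.6)
        mass = curve(bio_age_days) * indicated.bw_star * (1.0 + response * deviation)
        mass = max(mass, 0.0)
        organ_mass_total += mass
        organ_energy += mass * sigma
    residual = ffm - organ_mass_total
    if residual < 0:
        raise CompositionError(
            f"organ masses {organ_mass_total:.2f} kg exceed FFM {ffm:.2f} kg"
        )
    res_cell = cell if params.cellularity_applies_to_residual else 1.0
    return (organ_energy * cell + params.sigma_fm * fm
            + params.sigma_residual * residual * res_cell)


def growth_demand(v_fm_star: float, v_ffm_star: float, fm: float, ffm: float,
                  comp: CompositionParams, params: MetabolicParams
                  ) -> tuple[float, float, float]:
    """Energy needed to deposit the indicated mass velocities (MJ/day).

    Negative indicated velocities (aging decline) create no demand.  The
    FFM cost uses the marginal density at the current FFM; turnover is a
    configurable per-kg rate (default zero).
    """
    eff_fm = params.deposition_efficiency_fm
    eff_ffm = params.deposition_efficiency_ffm
    g_fm = max(0.0, v_fm_star) * comp.rho_fm / eff_fm
    g_ffm = max(0.0, v_ffm_star) * ffm_energy_density(ffm, comp) / eff_ffm
    turnover = params.turnover_rate * (fm + ffm)
    return g_fm, g_ffm, turnover


def tef(ei: float, params: MetabolicParams) -> float:
    """Thermic effect of feeding: a fixed fraction of intake."""
    if ei < 0:
        raise ParameterError("intake must be non-negative")
    return params.tef_fraction * ei


def adaptive_thermogenesis(ei: float, pre_at_demand: float, bmr: float,
                           params: MetabolicParams) -> float:
    """Signed expenditure adjustment from the intake/demand gap, applied to BMR.

    Negative under deficit (energy sparing), positive under surplus, zero at
    balance.  ``pre_at_demand`` is the demand for all other components and,
    by default, includes catch-up growth needs.
    """
    if pre_at_demand <= 0:
        raise ParameterError("pre-AT demand must be positive")
    return params.at_coefficient * (ei / pre_at_demand - 1.0) * bmr


def pa_demand(fm: float, ffm: float, curves: ReferenceCurveSet, subject: Subject,
              bio_age_days: float, params: MetabolicParams) -> float:
    """Physical-activity energy for the actual body weight.

    The reference PA curve describes a subject on the reference weight-for-age;
    with ``pa_scales_with_weight`` the cost scales with the mass moved.
    """
    pa = reference_pa(curves, subject, bio_age_days)
    if params.pa_scales_with_weight:
        h_star = subject.height_factor * (
            curves.height_ref(bio_age_days) + curves.height_race_offset)
        bw_ref = reference_bmi(curves, subject, bio_age_days) * h_star * h_star
        pa *= (fm + ffm) / bw_ref
    return pa


def total_demand(fm: float, ffm: float, indicated: IndicatedState,
                 curves: ReferenceCurveSet, subject: Subject, ei: float,
                 bio_age_days: float, comp: CompositionParams,
                 params: MetabolicParams,
                 indicated_velocities: tuple[float, float] = (0.0, 0.0),
                 extra_maintenance: float = 0.0) -> EnergyBudget:
    """Assemble the full itemized energy budget for one day.

    ``indicated_velocities`` are the desired deposition velocities of
    essential FM and FFM (kg/day), including any catch-up component; the
    simulator computes them from the motion of the indicated trajectory.
    ``extra_maintenance`` folds in maintenance-priority demands raised
    elsewhere (the composition-correction energy deficit).
    """
    bmr = bmr_demand(fm, ffm, indicated, curves, bio_age_days, params)
    pa = pa_demand(fm, ffm, curves, subject, bio_age_days, params)
    tef_e = tef(ei, params)
    g_fm, g_ffm, turnover = growth_demand(indicated_velocities[0], indicated_velocities[1],
                                          fm, ffm, comp, params)
    pre_at = bmr + pa + tef_e + turnover + extra_maintenance
    if params.at_includes_growth:
        pre_at += g_fm + g_ffm
    at = adaptive_thermogenesis(ei, pre_at, bmr, params)
    return EnergyBudget(bmr=bmr, pa=pa, tef=tef_e, growth_fm=g_fm,
                        growth_ffm=g_ffm, turnover=turnover, at_adjustment=at)
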