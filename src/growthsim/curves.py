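"""Age-indexed reference inputs that canalize growth.

Everything exogenous to the energy-balance dynamics lives here: the median
height-for-age curve (the attractor H* of height growth), the reference BMI
and fat-mass-index (FMI) curves, the reference physical-activity energy,
the organ composition table used by the organ-based basal-metabolic-rate
calculation, and the age profile of relative organ cellularity.

Curves are represented as shape-preserving piecewise-cubic (monotone
Hermite, PCHIP) interpolants through tabulated knots.  Monotone Hermite
interpolation never overshoots its knots, which matters because the first
derivative of the height curve feeds directly into the height-growth energy
demand.  Ages are handled in days internally; constructors accept years
where noted.

Two sources are supported: CDC-growth-chart-style LMS CSV tables (the
median, i.e. the M column, is used) and a parametric synthetic generator
that emulates the qualitative shape of the real charts so that every
simulation and test can run without any download.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import AgeSpanError, CurveFormatError, ParameterError

DAYS_PER_YEAR = 365.25

#: Additive adjustments (m) to the reference median height curve by race,
#: representing population-level height differences.  Values are defaults in
#: the absence of the survey-derived estimates and are overridable in config.
HEIGHT_RACE_OFFSETS: dict[str, float] = {
    "nh_white": 0.0,
    "nh_black": -0.004,
    "mexican_american": -0.036,
    "other": -0.010,
}

SEXES = ("male", "female")
RACES = tuple(HEIGHT_RACE_OFFSETS)


def years_to_days(y: float) -> float:
    return float(y) * DAYS_PER_YEAR


def days_to_years(d: float) -> float:
    return float(d) / DAYS_PER_YEAR


class AgeCurve:
    """A function of age (days) tabulated on strictly increasing knots.

    Evaluation outside ``[knots[0], knots[-1]]`` raises :class:`AgeSpanError`
    rather than extrapolating.
    """

    def __init__(self, ages_days: np.ndarray, values: np.ndarray, name: str = "curve"):
        ages_days = np.asarray(ages_days, dtype=float)
        values = np.asarray(values, dtype=float)
        if ages_days.ndim != 1 or ages_days.size < 2:
            raise CurveFormatError(f"{name}: need at least two knots")
        if not np.all(np.diff(ages_days) > 0):
            bad = int(np.flatnonzero(np.diff(ages_days) <= 0)[0]) + 1
            raise CurveFormatError(f"{name}: ages not strictly increasing at row {bad}")
        self.name = name
        self.ages = ages_days
        self.values = values
        self._interp = PchipInterpolator(ages_days, values, extrapolate=False)
        self._deriv = self._interp.derivative()

    @property
    def span(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def _check(self, age_days) -> np.ndarray:
        a = np.asarray(age_days, dtype=float)
        lo, hi = self.span
        # tolerate float chatter at the endpoints
        if np.any(a < lo - 1e-9) or np.any(a > hi + 1e-9):
            raise AgeSpanError(
                f"{self.name}: age {np.min(a):.3f}..{np.max(a):.3f} d outside "
                f"tabulated span [{lo:.1f}, {hi:.1f}] d"
            )
        return np.clip(a, lo, hi)

    def __call__(self, age_days):
        a = self._check(age_days)
        out = self._interp(a)
        # reproduce knot values exactly (interpolation introduces roundoff)
        idx = np.searchsorted(self.ages, a)
        idx = np.clip(idx, 0, self.ages.size - 1)
        exact = self.ages[idx] == a
        out = np.where(exact, self.values[idx], out)
        return float(out) if np.isscalar(age_days) else out

    def derivative(self, age_days):
        out = self._deriv(self._check(age_days))
        return float(out) if np.isscalar(age_days) else out

    def knot_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_days": self.ages, "value": self.values})


@dataclass(frozen=True)
class Subject:
    """Individual-variation descriptors.

    The neutral subject (all factors at their defaults) follows the
    population reference curves exactly.  ``height_factor`` multiplies the
    potential-height curve, ``bmi_factor`` the reference BMI (predisposition
    to higher BMI), ``fmi_offset`` (kg/m^2, may be negative) shifts body fat
    beyond the BMI/race expectation, ``pa_factor`` scales physical activity
    and ``bioage_multiplier`` maps calendar to biological age (slow growers
    < 1, fast growers > 1).
    """

    sex: str = "male"
    race: str = "nh_white"
    height_factor: float = 1.0
    bmi_factor: float = 1.0
    fmi_offset: float = 0.0
    pa_factor: float = 1.0
    bioage_multiplier: float = 1.0

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ParameterError(f"unknown sex {self.sex!r}")
        if self.race not in RACES:
            raise ParameterError(f"unknown race {self.race!r}")
        for name in ("height_factor", "bmi_factor", "bioage_multiplier"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and positive, got {v}")
        # pa_factor 0 is the bed-rest limit
        if not math.isfinite(self.pa_factor) or self.pa_factor < 0:
            raise ParameterError("pa_factor must be finite and >= 0")
        if not math.isfinite(self.fmi_offset):
            raise ParameterError("fmi_offset must be finite")


@dataclass(frozen=True)
class OrganTable:
    """Per-organ mass fractions of indicated body weight and specific
    metabolic rates (MJ per kg of organ per day)."""

    names: tuple[str, ...]
    fraction_curves: tuple[AgeCurve, ...]
    specific_rates: tuple[float, ...]  # MJ/(kg day)

    def fractions(self, age_days) -> np.ndarray:
        return np.array([c(age_days) for c in self.fraction_curves])

    def __post_init__(self):
        if not (len(self.names) == len(self.fraction_curves) == len(self.specific_rates)):
            raise ParameterError("organ table fields must have equal length")


@dataclass(frozen=True)
class ReferenceCurveSet:
    """All exogenous age-indexed inputs for one sex/race combination."""

    sex: str
    race: str
    height_ref: AgeCurve          # m
    bmi_ref: AgeCurve             # kg/m^2
    fmi_ref: AgeCurve             # kg/m^2 (includes post-childhood aging term)
    pa_ref: AgeCurve              # MJ/day at reference body weight
    organ_table: OrganTable
    cellularity: AgeCurve         # dimensionless in (0, 1]
    height_race_offset: float = 0.0   # m, additive
    adult_stop_age_days: float = 20.0 * DAYS_PER_YEAR

    @property
    def span(self) -> tuple[float, float]:
        los, his = zip(*(c.span for c in (self.height_ref, self.bmi_ref,
                                          self.fmi_ref, self.pa_ref)))
        return max(los), min(his)

    def export_knots(self, directory: str | Path) -> dict[str, Path]:
        """Write one CSV of knots per curve; values round-trip bit-identically."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        curves: dict[str, AgeCurve] = {
            "height": self.height_ref, "bmi": self.bmi_ref,
            "fmi": self.fmi_ref, "pa": self.pa_ref,
            "cellularity": self.cellularity,
        }
        for i, name in enumerate(self.organ_table.names):
            curves[f"organ_{name}"] = self.organ_table.fraction_curves[i]
        for name, curve in curves.items():
            path = directory / f"{name}_{self.sex}.csv"
            curve.knot_frame().to_csv(path, index=False, float_format="%.17g")
            written[name] = path
        return written


# ---------------------------------------------------------------------------
# Synthetic parametric reference curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCurveParams:
    """Shape parameters of the parametric reference curves.

    Defaults emulate the qualitative features of the CDC median charts:
    a smooth monotone height curve with high infant velocity, a childhood
    plateau and a single adolescent velocity peak that stops at adulthood;
    a BMI curve with an infancy bump, a childhood minimum and a rise to the
    adult level; sex-specific FMI curves with a linear post-childhood aging
    term; and a physical-activity reference that rises through adolescence
    and declines in old age.
    """

    # height (m, years)
    birth_height: float = 0.50
    adult_height: float = 1.77
    infancy_velocity: float = 0.28     # m/yr extra at birth, decaying
    infancy_tau_years: float = 0.8
    childhood_velocity: float = 0.055  # m/yr plateau
    spurt_age_years: float = 13.0
    spurt_sd_years: float = 1.0
    spurt_velocity: float = 0.045      # m/yr extra at the adolescent peak
    adult_stop_years: float = 20.0
    # BMI (kg/m^2)
    bmi_birth: float = 14.0
    bmi_min: float = 15.0
    bmi_adult: float = 22.0
    bmi_bump: float = 2.4
    bmi_bump_age_years: float = 0.75
    bmi_decay_years: float = 0.30
    bmi_rise_age_years: float = 13.0
    bmi_rise_width_years: float = 2.0
    # FMI (kg/m^2)
    fmi_birth: float = 1.8
    fmi_min: float = 2.2
    fmi_adult: float = 3.8
    fmi_bump: float = 2.4
    fmi_bump_age_years: float = 0.75
    fmi_decay_years: float = 0.40
    fmi_rise_age_years: float = 13.0
    fmi_rise_width_years: float = 2.5
    fmi_age_slope: float = 0.008       # kg/m^2 per year after adult_stop
    # physical activity: (years, MJ/day) knots before pa_level scaling
    pa_level: float = 1.0
    pa_knots: tuple[tuple[float, float], ...] = (
        (0, 0.30), (1, 0.60), (3, 1.10), (5, 1.50), (8, 2.10), (10, 2.50),
        (12, 2.90), (15, 3.20), (18, 3.10), (25, 2.90), (45, 2.90),
        (60, 2.60), (80, 2.10), (100, 1.70),
    )
    span_years: float = 100.0

    def __post_init__(self):
        if self.adult_height <= self.birth_height:
            raise ParameterError(
                f"adult height {self.adult_height} must exceed birth height {self.birth_height}"
            )
        if self.spurt_age_years >= self.adult_stop_years:
            raise ParameterError("growth spurt must precede the adult stop age")
        for name in ("birth_height", "bmi_birth", "bmi_min", "bmi_adult",
                     "fmi_birth", "fmi_min", "fmi_adult", "pa_level"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


FEMALE_OVERRIDES = dict(
    adult_height=1.63, spurt_age_years=11.0, spurt_velocity=0.040,
    bmi_adult=21.7, bmi_rise_age_years=12.0,
    fmi_birth=2.0, fmi_min=3.0, fmi_adult=6.5, fmi_bump=2.6,
    fmi_rise_age_years=12.0, fmi_rise_width_years=2.0, fmi_age_slope=0.010,
    pa_level=0.82,
)


def default_curve_params(sex: str) -> SyntheticCurveParams:
    if sex == "male":
        return SyntheticCurveParams()
    if sex == "female":
        return SyntheticCurveParams(**FEMALE_OVERRIDES)
    raise ParameterError(f"unknown sex {sex!r}")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _height_knots(p: SyntheticCurveParams) -> tuple[np.ndarray, np.ndarray]:
    stop = p.adult_stop_years
    fine = np.arange(0.0, stop + 1e-9, 1.0 / DAYS_PER_YEAR)  # daily, in years
    v = p.infancy_velocity * np.exp(-fine / p.infancy_tau_years)
    # childhood plateau tapering to zero at the adult stop
    w = np.where(
        fine <= p.spurt_age_years, 1.0,
        0.5 * (1.0 + np.cos(np.pi * np.clip(
            (fine - p.spurt_age_years) / (stop - p.spurt_age_years), 0, 1))),
    )
    v = v + p.childhood_velocity * w
    v = v + p.spurt_velocity * np.exp(-0.5 * ((fine - p.spurt_age_years) / p.spurt_sd_years) ** 2)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(fine))])
    scale = (p.adult_height - p.birth_height) / cum[-1]
    h_fine = p.birth_height + scale * cum
    # knots: monthly through the growth years, then the exact adult plateau
    knot_years = np.arange(0.0, stop, 1.0 / 12.0)
    h_knots = np.interp(knot_years, fine, h_fine)
    post = np.arange(stop, p.span_years + 1e-9, 1.0)
    knot_years = np.concatenate([knot_years, post])
    h_knots = np.concatenate([h_knots, np.full(post.size, p.adult_height)])
    return knot_years * DAYS_PER_YEAR, h_knots


def _bump_curve(x, birth, floor, bump, bump_age, decay, rise_to, rise_age, rise_width):
    """floor + infancy decay + infancy bump + adolescent logistic rise."""
    return (
        floor
        + (birth - floor) * np.exp(-x / decay)
        + bump * (x / bump_age) * np.exp(1.0 - x / bump_age)
        + (rise_to - floor) * _logistic((x - rise_age) / rise_width)
    )


def _bmi_knots(p: SyntheticCurveParams) -> tuple[np.ndarray, np.ndarray]:
    x = _knot_grid(p.span_years)
    y = _bump_curve(x, p.bmi_birth, p.bmi_min, p.bmi_bump, p.bmi_bump_age_years,
                    p.bmi_decay_years, p.bmi_adult, p.bmi_rise_age_years,
                    p.bmi_rise_width_years)
    return x * DAYS_PER_YEAR, y


def _fmi_knots(p: SyntheticCurveParams) -> tuple[np.ndarray, np.ndarray]:
    x = _knot_grid(p.span_years)
    y = _bump_curve(x, p.fmi_birth, p.fmi_min, p.fmi_bump, p.fmi_bump_age_years,
                    p.fmi_decay_years, p.fmi_adult, p.fmi_rise_age_years,
                    p.fmi_rise_width_years)
    y = y + p.fmi_age_slope * np.maximum(0.0, x - p.adult_stop_years)
    return x * DAYS_PER_YEAR, y


def _knot_grid(span_years: float) -> np.ndarray:
    child = np.arange(0.0, 25.0, 1.0 / 12.0)
    adult = np.arange(25.0, span_years + 1e-9, 1.0)
    return np.concatenate([child, adult])


# organ mass fractions of indicated body weight: (years, fraction) knots
_ORGAN_FRACTION_KNOTS: dict[str, tuple[tuple[float, float], ...]] = {
    "brain": ((0, 0.125), (0.5, 0.100), (1, 0.085), (2, 0.075), (5, 0.070),
              (10, 0.043), (15, 0.025), (20, 0.0195), (100, 0.0195)),
    "liver": ((0, 0.045), (1, 0.035), (5, 0.031), (10, 0.029), (20, 0.026),
              (100, 0.026)),
    "heart": ((0, 0.0065), (5, 0.0058), (10, 0.0052), (20, 0.0047), (100, 0.0047)),
    "kidneys": ((0, 0.0100), (1, 0.0075), (5, 0.0060), (10, 0.0050),
                (20, 0.0044), (100, 0.0044)),
}

#: specific metabolic rates, MJ per kg of organ per day
ORGAN_SPECIFIC_RATES: dict[str, float] = {
    "brain": 1.00, "liver": 0.84, "heart": 1.84, "kidneys": 1.84,
}

# Relative cellularity: the decline in mass-specific tissue metabolic rate
# from childhood through adulthood and old age (childhood tissue is more
# cellular and more metabolically intense per kg than adult tissue).
_CELLULARITY_KNOTS = ((0, 1.0), (5, 1.0), (10, 1.0), (15, 0.88), (20, 0.72),
                      (25, 0.675), (30, 0.663), (45, 0.64), (60, 0.615),
                      (80, 0.57), (100, 0.53))


def default_organ_table(span_years: float = 100.0) -> OrganTable:
    names, curves, rates = [], [], []
    for name, knots in _ORGAN_FRACTION_KNOTS.items():
        yrs, frac = zip(*knots)
        curves.append(AgeCurve(np.array(yrs) * DAYS_PER_YEAR, np.array(frac),
                               name=f"organ_{name}"))
        names.append(name)
        rates.append(ORGAN_SPECIFIC_RATES[name])
    return OrganTable(tuple(names), tuple(curves), tuple(rates))


def default_cellularity() -> AgeCurve:
    yrs, vals = zip(*_CELLULARITY_KNOTS)
    return AgeCurve(np.array(yrs) * DAYS_PER_YEAR, np.array(vals), name="cellularity")


def synthetic_reference(
    params: SyntheticCurveParams | None = None,
    sex: str = "male",
    race: str = "nh_white",
) -> ReferenceCurveSet:
    """Build a fully parametric reference-curve set (no external data).

    The generated set satisfies every ReferenceCurveSet invariant: monotone
    height with a single adolescent velocity peak and a hard stop at the
    adult age, strictly positive BMI/FMI/PA with the documented shapes, and
    organ fractions summing below one at every age.
    """
    p = params if params is not None else default_curve_params(sex)
    ha, hv = _height_knots(p)
    ba, bv = _bmi_knots(p)
    fa, fv = _fmi_knots(p)
    pa_yrs, pa_vals = zip(*p.pa_knots)
    pa_ages = np.array(pa_yrs, dtype=float) * DAYS_PER_YEAR
    pa_v = np.array(pa_vals, dtype=float) * p.pa_level
    if np.any(bv <= 0) or np.any(fv <= 0) or np.any(pa_v < 0):
        raise ParameterError("synthetic curve parameters produce non-positive values")
    if np.any(fv >= bv):
        raise ParameterError("synthetic FMI curve must stay below the BMI curve")
    return ReferenceCurveSet(
        sex=sex,
        race=race,
        height_ref=AgeCurve(ha, hv, name="height_ref"),
        bmi_ref=AgeCurve(ba, bv, name="bmi_ref"),
        fmi_ref=AgeCurve(fa, fv, name="fmi_ref"),
        pa_ref=AgeCurve(pa_ages, pa_v, name="pa_ref"),
        organ_table=default_organ_table(p.span_years),
        cellularity=default_cellularity(),
        height_race_offset=HEIGHT_RACE_OFFSETS[race],
        adult_stop_age_days=p.adult_stop_years * DAYS_PER_YEAR,
    )


# ---------------------------------------------------------------------------
# LMS CSV tables
# ---------------------------------------------------------------------------

def load_lms_curve(path: str | Path, name: str = "curve",
                   extend_to_days: float | None = None) -> AgeCurve:
    """Read one LMS-dialect CSV (``age_days,L,M,S`` or ``age_days,P50``).

    The 50th percentile of the LMS parameterisation is the M column, so the
    median curve is interpolated through M (or P50) with a shape-preserving
    piecewise cubic; knot values are reproduced exactly.  ``extend_to_days``
    appends a constant plateau at the last knot value (used for the adult
    height/BMI plateau when a chart table ends at age 20); it is an explicit
    opt-in, not silent extrapolation.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CurveFormatError(f"{path}: empty table") from None
    cols = {c.strip().lower(): c for c in df.columns}
    if "age_days" not in cols:
        raise CurveFormatError(f"{path}: missing required column 'age_days'")
    if "m" in cols:
        value_col = cols["m"]
    elif "p50" in cols:
        value_col = cols["p50"]
    else:
        raise CurveFormatError(f"{path}: need an 'M' (with L,S) or 'P50' column")
    if df.empty:
        raise CurveFormatError(f"{path}: empty table")
    ages = df[cols["age_days"]].to_numpy(dtype=float)
    vals = df[value_col].to_numpy(dtype=float)
    diffs = np.diff(ages)
    if np.any(~np.isfinite(ages)) or np.any(diffs <= 0):
        bad = int(np.flatnonzero(~(diffs > 0))[0]) + 2 if ages.size > 1 else 1
        raise CurveFormatError(f"{path}: ages not strictly increasing at data row {bad}")
    if extend_to_days is not None and extend_to_days > ages[-1]:
        ages = np.append(ages, extend_to_days)
        vals = np.append(vals, vals[-1])
    return AgeCurve(ages, vals, name=name)


def load_lms_table(
    height_path: str | Path,
    bmi_path: str | Path,
    sex: str,
    race: str = "nh_white",
    fmi_path: str | Path | None = None,
    pa_path: str | Path | None = None,
    extend_to_years: float | None = None,
    adult_stop_years: float = 20.0,
) -> ReferenceCurveSet:
    """Assemble a ReferenceCurveSet from LMS-dialect CSV files.

    Height and BMI tables are required (one file per sex per measure).  FMI
    and PA tables are optional; when omitted the synthetic parametric
    defaults for the requested sex are used for those curves.  Organ
    composition and cellularity always come from the built-in tables.
    """
    if sex not in SEXES:
        raise ParameterError(f"unknown sex {sex!r}")
    if race not in RACES:
        raise ParameterError(f"unknown race {race!r}")
    extend = None if extend_to_years is None else extend_to_years * DAYS_PER_YEAR
    defaults = synthetic_reference(sex=sex, race=race)
    height = load_lms_curve(height_path, name="height_ref", extend_to_days=extend)
    bmi = load_lms_curve(bmi_path, name="bmi_ref", extend_to_days=extend)
    fmi = (load_lms_curve(fmi_path, name="fmi_ref", extend_to_days=extend)
           if fmi_path else defaults.fmi_ref)
    pa = (load_lms_curve(pa_path, name="pa_ref", extend_to_days=extend)
          if pa_path else defaults.pa_ref)
    return ReferenceCurveSet(
        sex=sex, race=race, height_ref=height, bmi_ref=bmi, fmi_ref=fmi,
        pa_ref=pa, organ_table=defaults.organ_table,
        cellularity=defaults.cellularity,
        height_race_offset=HEIGHT_RACE_OFFSETS[race],
        adult_stop_age_days=adult_stop_years * DAYS_PER_YEAR,
    )


# ---------------------------------------------------------------------------
# Subject-adjusted evaluations
# ---------------------------------------------------------------------------

def biological_age(calendar_age_days: float, subject: Subject) -> float:
    """Map calendar age to the biological age driving the reference curves."""
    if calendar_age_days < 0:
        raise ParameterError("calendar age must be non-negative")
    return subject.bioage_multiplier * calendar_age_days


def indicated_height(curves: ReferenceCurveSet, subject: Subject, bio_age_days: float) -> float:
    """Potential height H*: individual factor times the race-adjusted median."""
    return subject.height_factor * (curves.height_ref(bio_age_days) + curves.height_race_offset)


def reference_bmi(curves: ReferenceCurveSet, subject: Subject, bio_age_days: float) -> float:
    """Subject-adjusted reference BMI for age."""
    return subject.bmi_factor * curves.bmi_ref(bio_age_days)


def reference_pa(curves: ReferenceCurveSet, subject: Subject, bio_age_days: float) -> float:
    """Reference physical-activity energy (MJ/day) for this subject and age."""
    return subject.pa_factor * curves.pa_ref(bio_age_days)
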