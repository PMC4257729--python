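"""Run configuration: a single YAML document from which a run is fully
reproducible.  Unknown keys are rejected with their key path; units in files
are days/kg/m/MJ, with kcal accepted at the intake interface
(1 kcal = 0.004184 MJ)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Sequence

import yaml

from .composition import CompositionParams
from .curves import (DAYS_PER_YEAR, ReferenceCurveSet, Subject,
                     SyntheticCurveParams, default_curve_params, load_lms_table,
                     synthetic_reference)
from .demand import MetabolicParams
from .errors import ConfigError
from .simulator import (BodyState, ModelParams, Scenario, SimParams,
                        reference_intake, reference_state)

KCAL_TO_MJ = 0.004184


@dataclass(frozen=True)
class CurvesConfig:
    source: str = "synthetic"            # synthetic | lms
    sex: str = "male"
    race: str = "nh_white"
    params: dict[str, Any] = field(default_factory=dict)   # synthetic overrides
    height_path: str | None = None
    bmi_path: str | None = None
    fmi_path: str | None = None
    pa_path: str | None = None
    extend_to_years: float | None = None


@dataclass(frozen=True)
class IntakeSegment:
    from_years: float = 0.0
    to_years: float = 0.0
    multiplier: float | None = None
    mj_per_day: float | None = None
    kcal_per_day: float | None = None
    delta_mj_per_day: float | None = None
    delta_kcal_per_day: float | None = None


@dataclass(frozen=True)
class IntakeConfig:
    mode: str = "reference"   # reference | constant | multiplier | piecewise
    mj_per_day: float | None = None
    kcal_per_day: float | None = None
    segments: tuple[IntakeSegment, ...] = ()


@dataclass(frozen=True)
class InitialConfig:
    kind: str = "reference"   # reference | explicit
    age_years: float | None = None
    weight_kg: float | None = None
    height_m: float | None = None
    fat_mass_kg: float | None = None
    bmi: float | None = None


@dataclass(frozen=True)
class ScenarioConfig:
    t_start_years: float = 0.0
    t_end_years: float = 20.0
    dt_days: float = 1.0
    intake: IntakeConfig = field(default_factory=IntakeConfig)
    initial: InitialConfig = field(default_factory=InitialConfig)


@dataclass(frozen=True)
class AnalysisConfig:
    kind: str = "maintenance_gap"
    ages_years: tuple[float, ...] = ()
    bmi_excess: float | None = None
    actual_bmi_csv: str | None = None
    delta_bmi: float = 1.0
    age_years: float = 30.0
    horizon_days: float = 365.0
    percentile_factor: float = 1.0
    target_weight_kg: float | None = None
    target_age_years: float | None = None
    observed_height_m: float | None = None
    observed_at_age_years: float | None = None


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "out"
    ledger: bool = False


@dataclass(frozen=True)
class RunConfig:
    curves: CurvesConfig = field(default_factory=CurvesConfig)
    subject: Subject = field(default_factory=Subject)
    composition: CompositionParams = field(default_factory=CompositionParams)
    metabolic: MetabolicParams = field(default_factory=MetabolicParams)
    simulation: SimParams = field(default_factory=SimParams)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output: OutputConfig = field(default_factory=OutputConfig)


def _build(cls, data: Any, path: str):
    """Recursively instantiate a dataclass from plain YAML data, rejecting
    unknown keys with their full key path."""
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        sub = _DATACLASS_FIELDS.get((cls, name))
        if sub is not None:
            if isinstance(sub, tuple):   # tuple of dataclasses
                inner = sub[0]
                if not isinstance(value, (list, tuple)):
                    raise ConfigError(f"{path}.{name}: expected a list")
                kwargs[name] = tuple(
                    _build(inner, v, f"{path}.{name}[{k}]") for k, v in enumerate(value))
            else:
                kwargs[name] = _build(sub, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


_DATACLASS_FIELDS: dict[tuple[type, str], Any] = {
    (RunConfig, "curves"): CurvesConfig,
    (RunConfig, "subject"): Subject,
    (RunConfig, "composition"): CompositionParams,
    (RunConfig, "metabolic"): MetabolicParams,
    (RunConfig, "simulation"): SimParams,
    (RunConfig, "scenario"): ScenarioConfig,
    (RunConfig, "analysis"): AnalysisConfig,
    (RunConfig, "output"): OutputConfig,
    (ScenarioConfig, "intake"): IntakeConfig,
    (ScenarioConfig, "initial"): InitialConfig,
    (IntakeConfig, "segments"): (IntakeSegment,),
}


def config_from_dict(data: dict) -> RunConfig:
    return _build(RunConfig, data, "config")


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return config_from_dict(data)


def _plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _plain(cfg)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_curves(cfg: CurvesConfig) -> ReferenceCurveSet:
    if cfg.source == "synthetic":
        base = default_curve_params(cfg.sex)
        params = dataclasses.replace(base, **{
            k: (tuple(map(tuple, v)) if k == "pa_knots" else v)
            for k, v in cfg.params.items()
        }) if cfg.params else base
        return synthetic_reference(params, sex=cfg.sex, race=cfg.race)
    if cfg.source == "lms":
        if not cfg.height_path or not cfg.bmi_path:
            raise ConfigError("curves: lms source requires height_path and bmi_path")
        return load_lms_table(cfg.height_path, cfg.bmi_path, cfg.sex, cfg.race,
                              cfg.fmi_path, cfg.pa_path, cfg.extend_to_years)
    raise ConfigError(f"curves.source must be 'synthetic' or 'lms', got {cfg.source!r}")


def build_params(cfg: RunConfig) -> ModelParams:
    return ModelParams(composition=cfg.composition, metabolic=cfg.metabolic,
                       sim=cfg.simulation)


def _segment_value(seg: IntakeSegment, base: float) -> float:
    given = [v is not None for v in (seg.multiplier, seg.mj_per_day, seg.kcal_per_day,
                                     seg.delta_mj_per_day, seg.delta_kcal_per_day)]
    if sum(given) != 1:
        raise ConfigError("intake segment needs exactly one of multiplier, "
                          "mj_per_day, kcal_per_day, delta_mj_per_day, delta_kcal_per_day")
    if seg.multiplier is not None:
        return seg.multiplier * base
    if seg.mj_per_day is not None:
        return seg.mj_per_day
    if seg.kcal_per_day is not None:
        return seg.kcal_per_day * KCAL_TO_MJ
    if seg.delta_mj_per_day is not None:
        return base + seg.delta_mj_per_day
    return base + seg.delta_kcal_per_day * KCAL_TO_MJ


def build_scenario(cfg: RunConfig, subject: Subject, curves: ReferenceCurveSet,
                   params: ModelParams) -> Scenario:
    sc = cfg.scenario
    t0 = sc.t_start_years * DAYS_PER_YEAR
    t1 = sc.t_end_years * DAYS_PER_YEAR
    init = None
    if sc.initial.kind == "explicit":
        ic = sc.initial
        age = (ic.age_years if ic.age_years is not None else sc.t_start_years) * DAYS_PER_YEAR
        if ic.weight_kg is not None:
            if ic.height_m is not None:
                h = ic.height_m
            else:
                h = reference_state(subject, curves, age, params).h
            bmi = ic.weight_kg / h ** 2
            st = reference_state(subject, curves, age, params, bmi=bmi)
            fm = ic.fat_mass_kg if ic.fat_mass_kg is not None else st.fm * (h / st.h) ** 2
            init = BodyState(fm=fm, ffm=ic.weight_kg - fm, h=h, age=age)
        elif ic.bmi is not None:
            init = reference_state(subject, curves, age, params, bmi=ic.bmi)
        else:
            raise ConfigError("scenario.initial: explicit start needs weight_kg+height_m or bmi")
    elif sc.initial.kind != "reference":
        raise ConfigError("scenario.initial.kind must be 'reference' or 'explicit'")

    intake = sc.intake
    if intake.mode == "constant":
        if intake.mj_per_day is not None:
            ei = intake.mj_per_day
        elif intake.kcal_per_day is not None:
            ei = intake.kcal_per_day * KCAL_TO_MJ
        else:
            raise ConfigError("scenario.intake: constant mode needs mj_per_day or kcal_per_day")
        return Scenario.constant(ei, t0, t1, sc.dt_days, init)
    if intake.mode == "reference":
        return Scenario(t0, t1, None, sc.dt_days, init)
    if intake.mode in ("multiplier", "piecewise"):
        ref = reference_intake(subject, curves, params, t0, t1 + sc.dt_days, sc.dt_days)
        segs = [(s.from_years * DAYS_PER_YEAR, s.to_years * DAYS_PER_YEAR, s)
                for s in intake.segments]

        def schedule(age: float) -> float:
            base = ref(age)
            for a0, a1, s in segs:
                if a0 <= age < a1:
                    return _segment_value(s, base)
            return base

        return Scenario(t0, t1, schedule, sc.dt_days, init)
    raise ConfigError(f"scenario.intake.mode {intake.mode!r} not recognised")


def build_all(cfg: RunConfig):
    """(subject, curves, params, scenario) from a validated config."""
    curves = build_curves(cfg.curves)
    subject = cfg.subject
    params = build_params(cfg)
    scenario = build_scenario(cfg, subject, curves, params)
    return subject, curves, params, scenario
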