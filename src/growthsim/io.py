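"""Run orchestration: execute a configured scenario or analysis, write the
result CSVs, the resolved-config snapshot, a log and a hashed manifest so
every run is reproducible from its artifacts alone."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import analyses as an
from .config import (RunConfig, build_all, build_curves, build_params,
                     config_to_dict, load_config, save_config)
from .curves import DAYS_PER_YEAR
from .errors import ConfigError
from .simulator import reference_intake, simulate

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_digest(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_to_dict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _finalize(outdir: Path, cfg: RunConfig, written: list[Path]) -> dict[str, str]:
    snap = outdir / "resolved_config.yaml"
    save_config(cfg, snap)
    written.append(snap)
    manifest = {p.name: _digest(p) for p in written}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _setup(cfg: RunConfig, outdir: str | Path | None) -> Path:
    out = Path(outdir if outdir is not None else cfg.output.directory)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("growthsim")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("growthsim %s, config digest %s", __version__, _config_digest(cfg))
    return out


def run_scenario(config: RunConfig | str | Path,
                 outdir: str | Path | None = None) -> dict[str, str]:
    """Simulate the configured scenario; writes result.csv (one row per day),
    the resolved config, run.log and manifest.json.  Returns the manifest."""
    cfg = load_config(config) if not isinstance(config, RunConfig) else config
    out = _setup(cfg, outdir)
    subject, curves, params, scenario = build_all(cfg)
    result = simulate(subject, curves, scenario, params)
    logger.info("simulated %d steps (%.1f-%.1f y), collapsed=%s",
                result.n_steps, scenario.t_start / DAYS_PER_YEAR,
                scenario.t_end / DAYS_PER_YEAR, result.collapsed)
    written = []
    rpath = out / "result.csv"
    result.to_dataframe().to_csv(rpath, index=False, float_format="%.10g")
    written.append(rpath)
    if cfg.output.ledger:
        lpath = out / "budget_ledger.csv"
        cols = ["age", "ei", "bmr", "pa", "tef", "at", "turnover",
                "growth_fm_demand", "growth_ffm_demand", "losses",
                "catabolized", "stored", "expended"]
        result.to_dataframe()[cols].to_csv(lpath, index=False, float_format="%.10g")
        written.append(lpath)
    return _finalize(out, cfg, written)


def run_analysis(config: RunConfig | str | Path, kind: str | None = None,
                 outdir: str | Path | None = None) -> dict[str, str]:
    """Dispatch one of the applied analyses configured in the ``analysis``
    config block; writes an analysis CSV/JSON plus the usual run artifacts."""
    cfg = load_config(config) if not isinstance(config, RunConfig) else config
    out = _setup(cfg, outdir)
    acfg = cfg.analysis
    kind = kind or acfg.kind
    subject = cfg.subject
    curves = build_curves(cfg.curves)
    params = build_params(cfg)
    written: list[Path] = []

    if kind == "maintenance_gap":
        if acfg.actual_bmi_csv:
            tab = pd.read_csv(acfg.actual_bmi_csv)
            if not {"age_years", "bmi"} <= set(tab.columns):
                raise ConfigError("actual_bmi_csv needs columns age_years,bmi")
            ages = tab["age_years"].to_numpy(float) * DAYS_PER_YEAR
            vals = tab["bmi"].to_numpy(float)
            curve = lambda a: float(np.interp(a, ages, vals))
        elif acfg.bmi_excess is not None:
            curve = an.shifted_reference_bmi(curves, acfg.bmi_excess)
        else:
            curve = an.shifted_reference_bmi(curves, 0.0)
        grid = list(acfg.ages_years) or None
        report = an.maintenance_energy_gap(subject, curves, curve, params, grid)
        path = out / "maintenance_gap.csv"
        report.to_dataframe().to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        logger.info("maintenance gap: mean %.3f MJ/day (%.1f%% of intake)",
                    report.mean_absolute, 100 * report.mean_fractional)
    elif kind == "energy_gap":
        gap, frac = an.weight_loss_energy_gap(subject, curves, acfg.delta_bmi,
                                              acfg.age_years, params,
                                              acfg.horizon_days)
        path = out / "energy_gap.json"
        path.write_text(json.dumps({"delta_bmi": acfg.delta_bmi,
                                    "age_years": acfg.age_years,
                                    "absolute_gap_mj": gap,
                                    "fractional_gap": frac}, indent=2) + "\n")
        written.append(path)
    elif kind == "percentile":
        curve = an.scaled_reference_bmi(curves, acfg.percentile_factor)
        res = an.percentile_tracking_intake(
            subject, curves, curve, params,
            t_end=cfg.scenario.t_end_years * DAYS_PER_YEAR,
            dt=cfg.scenario.dt_days)
        path = out / "percentile_tracking.csv"
        res.to_dataframe().to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    elif kind == "calibrate":
        report = {}
        if acfg.target_weight_kg is not None:
            if acfg.target_age_years is None:
                raise ConfigError("analysis: target_age_years required with target_weight_kg")
            report["intake_multiplier"] = an.calibrate_intake_multiplier(
                subject, curves, acfg.target_weight_kg, acfg.target_age_years, params)
        if acfg.observed_height_m is not None:
            if acfg.observed_at_age_years is None:
                raise ConfigError("analysis: observed_at_age_years required")
            report["height_factor"] = an.calibrate_height_factor(
                subject, curves, acfg.observed_height_m,
                acfg.observed_at_age_years, params)
        if not report:
            raise ConfigError("analysis: calibrate needs a weight or height target")
        path = out / "calibration.json"
        path.write_text(json.dumps(report, indent=2) + "\n")
        written.append(path)
    else:
        raise ConfigError(f"unknown analysis kind {kind!r}")
    return _finalize(out, cfg, written)
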