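"""Run configuration (YAML), CSV output, and deterministic formatting.

A run configuration names a shipped preset plus scalar overrides, or
spells out a scenario inline.  Concentrations are accepted in mM
(numerically mol m^-3 for aqueous solutions), pressures in Pa, times in
seconds or with an explicit ``s``/``min``/``h`` suffix.

All output files start with a comment header carrying the tool version
and a hash of the inputs, and all numbers are written in scientific
notation with 9 significant digits so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .dynamics import EventResult, Scenario, SolverSettings, TimeSeries
from .fixtures import preset, preset_names
from .submodels import (
    BulkModulusLaw,
    ConfigurationError,
    FoulingLaw,
    Membrane,
    OsmoticLaw,
    VolumeLaw,
    WorkingFluid,
    volume_and_derivative,
)

logger = logging.getLogger("osmodyn")

FLOAT_FORMAT = "%.9e"

_TIME_UNITS = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0}

#: Scalar scenario fields that a preset override may touch.
OVERRIDE_KEYS = frozenset(
    {
        "lp0",
        "area_m2",
        "area_cm2",
        "sigma",
        "moles_solute",
        "concentration_mM",
        "p_initial_Pa",
        "external_osmotic_pressure_Pa",
        "t_end",
        "mode",
        "rel_tol",
        "abs_tol",
        "events_Pa",
    }
)


def parse_time(value: Any) -> float:
    """Parse a time in seconds from a number or a ``"<number> <unit>"`` string."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-zA-Z]*)\s*", str(value))
    if not m:
        raise ConfigurationError(f"cannot parse time value {value!r}")
    num, unit = m.group(1), m.group(2).lower() or "s"
    if unit not in _TIME_UNITS:
        raise ConfigurationError(
            f"unknown time unit {unit!r} in {value!r}; use s, min or h"
        )
    try:
        return float(num) * _TIME_UNITS[unit]
    except ValueError as exc:
        raise ConfigurationError(f"cannot parse time value {value!r}") from exc


def _require_number(d: dict, key: str, *, positive: bool = False) -> float:
    if key not in d:
        raise ConfigurationError(f"missing required key {key!r}")
    v = d[key]
    if not isinstance(v, (int, float)):
        raise ConfigurationError(f"key {key!r} must be a number, got {v!r}")
    if positive and v <= 0:
        raise ConfigurationError(f"key {key!r} must be positive, got {v}")
    return float(v)


def _check_keys(d: dict, allowed: set[str], ctx: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {ctx}: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """A validated run: the scenario, output paths and reporting options."""

    scenario: Scenario
    timeseries_path: str | None = None
    events_path: str | None = None
    report_points: int = 512
    log_level: str = "INFO"
    source: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.report_points < 2:
            raise ConfigurationError("report_points must be >= 2")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigurationError(f"unknown log_level {self.log_level!r}")


# ---------------------------------------------------------------------------
# Scenario <-> dict
# ---------------------------------------------------------------------------

def _osmotic_law_from_dict(d: dict) -> OsmoticLaw:
    _check_keys(
        d, {"mode", "a1", "a2", "a3", "osmotic_coefficient", "temperature_K"},
        "osmotic_law",
    )
    return OsmoticLaw(
        mode=d.get("mode", "vant_hoff"),
        a1=float(d.get("a1", 0.0)),
        a2=float(d.get("a2", 0.0)),
        a3=float(d.get("a3", 0.0)),
        osmotic_coefficient=float(d.get("osmotic_coefficient", 1.0)),
        temperature=float(d.get("temperature_K", 298.15)),
    )


def _volume_law_from_dict(d: dict) -> VolumeLaw:
    _check_keys(
        d,
        {"variant", "v_ref_m3", "v_ref_ml", "alpha", "beta", "compliance", "table"},
        "volume_law",
    )
    if "v_ref_ml" in d and "v_ref_m3" in d:
        raise ConfigurationError("give v_ref_m3 or v_ref_ml, not both")
    v_ref = float(d.get("v_ref_m3", 0.0))
    if "v_ref_ml" in d:
        v_ref = float(d["v_ref_ml"]) * 1e-6
    table = d.get("table")
    if table is not None:
        table = tuple((float(p), float(v)) for p, v in table)
    return VolumeLaw(
        variant=d.get("variant", "constant"),
        v_ref=v_ref,
        alpha=float(d.get("alpha", 0.0)),
        beta=float(d.get("beta", 0.0)),
        compliance=float(d.get("compliance", 0.0)),
        table=table,
    )


def scenario_from_dict(d: dict) -> Scenario:
    """Build a scenario from an inline configuration dictionary."""
    _check_keys(
        d,
        {
            "fluid",
            "membrane",
            "volume_law",
            "mode",
            "p_initial_Pa",
            "external_osmotic_pressure_Pa",
            "t_end",
            "events_Pa",
            "rel_tol",
            "abs_tol",
            "name",
        },
        "scenario",
    )
    for section in ("fluid", "membrane", "volume_law"):
        if section not in d or not isinstance(d[section], dict):
            raise ConfigurationError(f"missing or invalid section {section!r}")
    fd = d["fluid"]
    _check_keys(
        fd,
        {
            "moles_solute",
            "concentration_mM",
            "osmotic_law",
            "fouling_law",
            "bulk_law",
            "rho_solvent",
            "rho_atm_intercept",
            "rho_atm_slope",
        },
        "fluid",
    )
    vol_law = _volume_law_from_dict(d["volume_law"])
    p_initial = float(d.get("p_initial_Pa", 0.0))
    if "moles_solute" in fd and "concentration_mM" in fd:
        raise ConfigurationError("give moles_solute or concentration_mM, not both")
    if "concentration_mM" in fd:
        c0 = float(fd["concentration_mM"])  # mM == mol m^-3
        if c0 < 0:
            raise ConfigurationError("concentration_mM must be non-negative")
        v0 = volume_and_derivative(p_initial, vol_law)[0]
        moles = c0 * v0
    else:
        moles = _require_number(fd, "moles_solute")
    fl = fd.get("fouling_law", {})
    _check_keys(fl, {"f_max", "c_half_mM", "hill_n"}, "fouling_law")
    md = d["membrane"]
    _check_keys(md, {"lp0", "area_m2", "area_cm2", "sigma", "mwco_label"}, "membrane")
    if "area_m2" in md and "area_cm2" in md:
        raise ConfigurationError("give area_m2 or area_cm2, not both")
    area = float(md.get("area_m2", 0.0))
    if "area_cm2" in md:
        area = float(md["area_cm2"]) * 1e-4
    bd = fd.get("bulk_law", {})
    _check_keys(bd, {"k0", "k1", "k2", "kp"}, "bulk_law")
    fluid = WorkingFluid(
        moles_solute=moles,
        osmotic_law=_osmotic_law_from_dict(fd.get("osmotic_law", {})),
        fouling_law=FoulingLaw(
            f_max=float(fl.get("f_max", 0.0)),
            c_half=float(fl.get("c_half_mM", 1.0)),
            hill_n=float(fl.get("hill_n", 1.0)),
        ),
        bulk_law=BulkModulusLaw(
            k0=float(bd.get("k0", BulkModulusLaw().k0)),
            k1=float(bd.get("k1", 0.0)),
            k2=float(bd.get("k2", 0.0)),
            kp=float(bd.get("kp", 0.0)),
        ),
        rho_solvent=float(fd.get("rho_solvent", WorkingFluid(0).rho_solvent)),
        rho_atm_intercept=float(
            fd.get("rho_atm_intercept", WorkingFluid(0).rho_atm_intercept)
        ),
        rho_atm_slope=float(fd.get("rho_atm_slope", WorkingFluid(0).rho_atm_slope)),
    )
    membrane = Membrane(
        lp0=_require_number(md, "lp0", positive=True),
        area=area,
        sigma=float(md.get("sigma", 1.0)),
        mwco_label=str(md.get("mwco_label", "")),
    )
    events = tuple(float(g) for g in d.get("events_Pa", ()))
    solver = SolverSettings(
        rel_tol=float(d.get("rel_tol", SolverSettings().rel_tol)),
        abs_tol=float(d.get("abs_tol", SolverSettings().abs_tol)),
    )
    return Scenario(
        fluid=fluid,
        membrane=membrane,
        volume_law=vol_law,
        mode=str(d.get("mode", "pressurize")),
        p_initial=p_initial,
        external_osmotic_pressure=float(d.get("external_osmotic_pressure_Pa", 0.0)),
        t_end=parse_time(d.get("t_end", 3600.0)),
        solver=solver,
        events=events,
        name=str(d.get("name", "")),
    )


def scenario_to_dict(s: Scenario) -> dict:
    """Serializable inline representation; round-trips through
    ``scenario_from_dict``."""
    fluid, mem, vl = s.fluid, s.membrane, s.volume_law
    d: dict[str, Any] = {
        "fluid": {
            "moles_solute": fluid.moles_solute,
            "osmotic_law": {
                "mode": fluid.osmotic_law.mode,
                "a1": fluid.osmotic_law.a1,
                "a2": fluid.osmotic_law.a2,
                "a3": fluid.osmotic_law.a3,
                "osmotic_coefficient": fluid.osmotic_law.osmotic_coefficient,
                "temperature_K": fluid.osmotic_law.temperature,
            },
            "fouling_law": {
                "f_max": fluid.fouling_law.f_max,
                "c_half_mM": fluid.fouling_law.c_half,
                "hill_n": fluid.fouling_law.hill_n,
            },
            "bulk_law": {
                "k0": fluid.bulk_law.k0,
                "k1": fluid.bulk_law.k1,
                "k2": fluid.bulk_law.k2,
                "kp": fluid.bulk_law.kp,
            },
            "rho_solvent": fluid.rho_solvent,
            "rho_atm_intercept": fluid.rho_atm_intercept,
            "rho_atm_slope": fluid.rho_atm_slope,
        },
        "membrane": {
            "lp0": mem.lp0,
            "area_m2": mem.area,
            "sigma": mem.sigma,
            "mwco_label": mem.mwco_label,
        },
        "volume_law": {
            "variant": vl.variant,
            "v_ref_m3": vl.v_ref,
            "alpha": vl.alpha,
            "beta": vl.beta,
            "compliance": vl.compliance,
        },
        "mode": s.mode,
        "p_initial_Pa": s.p_initial,
        "external_osmotic_pressure_Pa": s.external_osmotic_pressure,
        "t_end": s.t_end,
        "rel_tol": s.solver.rel_tol,
        "abs_tol": s.solver.abs_tol,
        "events_Pa": list(s.events),
        "name": s.name,
    }
    if vl.table is not None:
        d["volume_law"]["table"] = [[p, v] for p, v in vl.table]
    return d


# ---------------------------------------------------------------------------
# Preset overrides
# ---------------------------------------------------------------------------

def apply_overrides(scenario: Scenario, overrides: dict) -> Scenario:
    """Apply whitelisted scalar overrides to a preset scenario."""
    _check_keys(overrides, set(OVERRIDE_KEYS), "overrides")
    s = scenario
    mem = s.membrane
    if "lp0" in overrides:
        v = float(overrides["lp0"])
        if v <= 0:
            raise ConfigurationError(f"override lp0 must be positive, got {v}")
        mem = replace(mem, lp0=v)
    if "area_m2" in overrides and "area_cm2" in overrides:
        raise ConfigurationError("give area_m2 or area_cm2, not both")
    if "area_m2" in overrides:
        mem = replace(mem, area=float(overrides["area_m2"]))
    if "area_cm2" in overrides:
        mem = replace(mem, area=float(overrides["area_cm2"]) * 1e-4)
    if "sigma" in overrides:
        mem = replace(mem, sigma=float(overrides["sigma"]))
    s = replace(s, membrane=mem)
    fluid = s.fluid
    if "moles_solute" in overrides and "concentration_mM" in overrides:
        raise ConfigurationError("give moles_solute or concentration_mM, not both")
    if "moles_solute" in overrides:
        fluid = replace(fluid, moles_solute=float(overrides["moles_solute"]))
    if "concentration_mM" in overrides:
        c0 = float(overrides["concentration_mM"])
        p0 = float(overrides.get("p_initial_Pa", s.p_initial))
        v0 = volume_and_derivative(p0, s.volume_law)[0]
        fluid = replace(fluid, moles_solute=c0 * v0)
    s = replace(s, fluid=fluid)
    if "p_initial_Pa" in overrides:
        s = replace(s, p_initial=float(overrides["p_initial_Pa"]))
    if "external_osmotic_pressure_Pa" in overrides:
        s = replace(
            s, external_osmotic_pressure=float(overrides["external_osmotic_pressure_Pa"])
        )
    if "t_end" in overrides:
        s = replace(s, t_end=parse_time(overrides["t_end"]))
    if "mode" in overrides:
        s = replace(s, mode=str(overrides["mode"]))
    if "rel_tol" in overrides or "abs_tol" in overrides:
        s = replace(
            s,
            solver=replace(
                s.solver,
                rel_tol=float(overrides.get("rel_tol", s.solver.rel_tol)),
                abs_tol=float(overrides.get("abs_tol", s.solver.abs_tol)),
            ),
        )
    if "events_Pa" in overrides:
        s = replace(s, events=tuple(float(g) for g in overrides["events_Pa"]))
    return s


# ---------------------------------------------------------------------------
# RunConfig load/dump
# ---------------------------------------------------------------------------

def config_from_dict(doc: dict) -> RunConfig:
    _check_keys(
        doc, {"scenario", "outputs", "report_points", "log_level"}, "config"
    )
    if "scenario" not in doc or not isinstance(doc["scenario"], dict):
        raise ConfigurationError("config must contain a 'scenario' mapping")
    sd = doc["scenario"]
    _check_keys(sd, {"preset", "overrides", "inline"}, "scenario block")
    if ("preset" in sd) == ("inline" in sd):
        raise ConfigurationError("scenario must name a preset OR be inline, not both")
    if "preset" in sd:
        scenario = preset(str(sd["preset"]))
        overrides = sd.get("overrides", {})
        if overrides:
            scenario = apply_overrides(scenario, overrides)
    else:
        if "overrides" in sd:
            raise ConfigurationError("overrides apply to presets only")
        scenario = scenario_from_dict(sd["inline"])
    outputs = doc.get("outputs", {}) or {}
    _check_keys(outputs, {"timeseries", "events"}, "outputs")
    return RunConfig(
        scenario=scenario,
        timeseries_path=outputs.get("timeseries"),
        events_path=outputs.get("events"),
        report_points=int(doc.get("report_points", 512)),
        log_level=str(doc.get("log_level", "INFO")),
        source=doc,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config file {path} is not a YAML mapping")
    return config_from_dict(doc)


def dump_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML so that load(dump(cfg)) == cfg."""
    doc = {
        "scenario": {"inline": scenario_to_dict(cfg.scenario)},
        "outputs": {
            k: v
            for k, v in (
                ("timeseries", cfg.timeseries_path),
                ("events", cfg.events_path),
            )
            if v
        },
        "report_points": cfg.report_points,
        "log_level": cfg.log_level,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

def input_hash(scenario: Scenario, extra: dict | None = None) -> str:
    """Short content hash of the scenario (and any extra inputs)."""
    payload = {"scenario": scenario_to_dict(scenario)}
    if extra:
        payload["extra"] = extra
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header(scenario: Scenario, extra: dict | None = None) -> str:
    return f"# osmodyn {__version__} input_hash={input_hash(scenario, extra)}\n"


def write_timeseries(ts: TimeSeries, path, extra: dict | None = None) -> None:
    """Write a trajectory CSV with the canonical columns and header comment."""
    assert ts.scenario is not None
    with open(path, "w") as fh:
        fh.write(_header(ts.scenario, extra))
        ts.to_frame().to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_events(
    results: Sequence[EventResult], scenario: Scenario, path, extra: dict | None = None
) -> None:
    """Write threshold-crossing results: gain_Pa, time_s, reached."""
    df = pd.DataFrame(
        {
            "gain_Pa": [r.threshold for r in results],
            "time_s": [r.time if r.time is not None else float("nan") for r in results],
            "reached": [r.reached for r in results],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header(scenario, extra))
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_timeseries_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


__all__ = [
    "FLOAT_FORMAT",
    "OVERRIDE_KEYS",
    "RunConfig",
    "parse_time",
    "scenario_from_dict",
    "scenario_to_dict",
    "apply_overrides",
    "config_from_dict",
    "load_config",
    "dump_config",
    "input_hash",
    "write_timeseries",
    "write_events",
    "read_timeseries_csv",
    "logger",
]
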