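"""Versioned YAML run configuration.

A config file has up to five sections — ``grid``, ``run``,
``transport``, ``transform`` and ``scenario`` — all optional, all
validated against a closed key schema (unknown keys are rejected so
typos fail loudly instead of silently using defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .biogeochem import TransformParams
from .engine import RunConfig, ScenarioSpec
from .terrain import TransportParams

__all__ = ["AppConfig", "load_config", "default_config_text"]

SCHEMA_VERSION = 1

_GRID_KEYS = {"kind", "n_rows", "n_cols", "cell_size", "relief", "seed"}
_RUN_KEYS = {
    "duration_years", "start_year", "reporting_interval_days", "tillage_month",
    "tillage_depth", "transport_enabled", "seed", "diffusivity_m2_yr", "k_soc",
    "infiltration_capacity_mm", "drainage_coefficient", "routing_interval_days",
}
_TRANSPORT_KEYS = {"k_t", "m_exp", "n_exp", "k_d", "dc_exp"}
_TRANSFORM_KEYS = {
    "k_l", "k_h", "r_r", "r_h", "phi", "mortality", "d0_bioturb", "z_bioturb",
    "litter_surface_fraction", "root_depth", "root_efold",
}
_SCENARIO_KEYS = {"litter_multiplier", "target_mrt_years"}


class ConfigError(ValueError):
    pass


@dataclass
class AppConfig:
    """Parsed configuration: synthetic-grid spec plus engine config."""

    grid: dict = field(default_factory=dict)
    run: RunConfig = field(default_factory=RunConfig)
    raw_text: str = ""


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")


def load_config(path) -> AppConfig:
    """Load and validate a YAML config file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("root", doc, {"version", "grid", "run", "transport",
                              "transform", "scenario"})
    version = doc.get("version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported config version {version}")

    grid = doc.get("grid", {}) or {}
    _check_keys("grid", grid, _GRID_KEYS)

    run_sec = dict(doc.get("run", {}) or {})
    _check_keys("run", run_sec, _RUN_KEYS)
    if "diffusivity_m2_yr" in run_sec:
        run_sec["diffusivity"] = run_sec.pop("diffusivity_m2_yr") / 365.0

    tp = doc.get("transport", {}) or {}
    _check_keys("transport", tp, _TRANSPORT_KEYS)
    tf = doc.get("transform", {}) or {}
    _check_keys("transform", tf, _TRANSFORM_KEYS)
    sc = doc.get("scenario", None)
    scenario = None
    if sc:
        _check_keys("scenario", sc, _SCENARIO_KEYS)
        scenario = ScenarioSpec(**sc)

    try:
        cfg = RunConfig(transport=TransportParams(**tp),
                        transform=TransformParams(**tf),
                        scenario=scenario, **run_sec)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return AppConfig(grid=grid, run=cfg, raw_text=text)


def default_config_text() -> str:
    """A complete, commented example configuration."""
    return """\
version: 1
grid:
  kind: consolidated      # natural | consolidated
  n_rows: 32
  n_cols: 32
  cell_size: 2.0          # m
  relief: 15.0            # total vertical range, m
  seed: 0
run:
  duration_years: 50
  start_year: 2021
  transport_enabled: true
  seed: 0
  diffusivity_m2_yr: 0.002
  k_soc: 1.0
transform:
  r_r: 0.7
  r_h: 0.2
# scenario:               # uncomment for a management run
#   litter_multiplier: 1.0
#   target_mrt_years: 15.8
"""
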