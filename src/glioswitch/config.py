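"""Structured-text (YAML) configuration for scenarios and parameter sets.

A config document is a nested mapping with the sections ``switch``,
``pde``, ``grid``, ``schedule``, ``stepper``, ``scenario`` — every key
optional, every omitted key defaulting to the reference parameterization.
Unknown keys are rejected by name so typos cannot silently fall back to
defaults, and a loaded document serializes back to an identical document.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict
from pathlib import Path
from typing import Any

import yaml

from glioswitch.simulator import ConstantSupply, ScenarioConfig, TimeStepper
from glioswitch.spatial_model import Grid1D, InjectionSchedule, PDEParams
from glioswitch.switch_network import SwitchParams

__all__ = ["ConfigError", "load_config", "dump_config", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_SECTIONS = ("switch", "pde", "grid", "schedule", "stepper", "scenario")

_SCENARIO_KEYS = {
    "name": str,
    "t_end": float,
    "output_dt": float,
    "debounce": float,
    "initial": dict,
}


class ConfigError(ValueError):
    """Schema violation: names the offending key and constraint."""


def _build(cls, section: str, data: dict, **extra) -> Any:
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in valid:
            raise ConfigError(
                f"unknown key {key!r} in section {section!r}; valid keys: {sorted(valid)}")
    try:
        return cls(**data, **extra)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(source: str | Path | dict | None = None) -> ScenarioConfig:
    """Build a fully-defaulted ScenarioConfig from YAML text, a path, or a dict.

    An empty document yields the reference configuration (all defaults).
    ``schedule`` may carry ``kind: pulsed`` (default) or ``kind: constant``
    (continuous supply with a ``rate``); ``schedule: null`` disables the
    glucose source entirely.
    """
    if source is None:
        doc: dict = {}
    elif isinstance(source, dict):
        doc = dict(source)
    else:
        if isinstance(source, Path):
            text = source.read_text()
        elif source.strip() and "\n" not in source and Path(source).is_file():
            text = Path(source).read_text()
        else:
            text = source
        doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    for key in doc:
        if key not in _SECTIONS and key != "schema_version":
            raise ConfigError(f"unknown top-level section {key!r}; valid: {list(_SECTIONS)}")

    switch = _build(SwitchParams, "switch", doc.get("switch") or {})
    pde_data = dict(doc.get("pde") or {})
    if "switch" in pde_data:
        raise ConfigError("put switch parameters in the 'switch' section, not under 'pde'")
    pde = _build(PDEParams, "pde", pde_data, switch=switch)
    grid = _build(Grid1D, "grid", doc.get("grid") or {})

    if "schedule" in doc and doc["schedule"] is None:
        schedule = None
    else:
        sched_data = dict(doc.get("schedule") or {})
        kind = sched_data.pop("kind", "pulsed")
        if kind == "pulsed":
            schedule = _build(InjectionSchedule, "schedule", sched_data)
        elif kind == "constant":
            schedule = _build(ConstantSupply, "schedule", sched_data)
        else:
            raise ConfigError(f"schedule.kind must be 'pulsed' or 'constant', got {kind!r}")

    scen = dict(doc.get("scenario") or {})
    for key in scen:
        if key not in _SCENARIO_KEYS:
            raise ConfigError(
                f"unknown key {key!r} in section 'scenario'; valid keys: {sorted(_SCENARIO_KEYS)}")
    stepper = _build(TimeStepper, "stepper", doc.get("stepper") or {})

    cfg = ScenarioConfig(
        name=scen.get("name", "default"),
        grid=grid,
        params=pde,
        schedule=schedule,
        t_end=float(scen.get("t_end", 100.0)),
        output_dt=float(scen.get("output_dt", 1.0)),
        initial=dict(scen.get("initial", {})),
        debounce=float(scen.get("debounce", 0.5)),
        stepper=stepper,
    )
    _validate(cfg)
    return cfg


def _validate(cfg: ScenarioConfig) -> None:
    if isinstance(cfg.schedule, InjectionSchedule):
        if cfg.schedule.duration >= cfg.schedule.tau:
            raise ConfigError("schedule.duration must be < schedule.tau")
    if cfg.t_end <= 0:
        raise ConfigError("scenario.t_end must be positive")
    if cfg.output_dt <= 0:
        raise ConfigError("scenario.output_dt must be positive")


def dump_config(cfg: ScenarioConfig) -> dict:
    """Serialize a ScenarioConfig back to a plain config document."""
    pde = asdict(cfg.params)
    switch = pde.pop("switch")
    if cfg.schedule is None:
        schedule = None
    elif isinstance(cfg.schedule, ConstantSupply):
        schedule = {"kind": "constant", **asdict(cfg.schedule)}
    else:
        schedule = {"kind": "pulsed", **asdict(cfg.schedule)}
    return {
        "schema_version": SCHEMA_VERSION,
        "switch": switch,
        "pde": pde,
        "grid": {"n_cells": cfg.grid.n_cells},
        "schedule": schedule,
        "stepper": asdict(cfg.stepper),
        "scenario": {
            "name": cfg.name,
            "t_end": cfg.t_end,
            "output_dt": cfg.output_dt,
            "debounce": cfg.debounce,
            "initial": dict(cfg.initial),
        },
    }
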