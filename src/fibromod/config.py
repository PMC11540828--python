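"""Run configuration: YAML parsing, validation and defaults.

A single YAML file configures all pipeline stages; every field has a
default, so an empty file is a valid configuration.  Validation collects
*all* problems (with the offending field path) rather than stopping at the
first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import NetworkParams
from .project import ProjectionParams
from .simulate import ModulePlan, SimulationConfig, default_module_plans


@dataclass
class RunConfig:
    simulation: SimulationConfig
    network: NetworkParams
    projection: ProjectionParams
    da_threshold: float = 2.5
    seed: int = 0
    outdir: str = "fibromod_out"
    stages: tuple[str, ...] = (
        "simulate", "deg", "network", "phase-da", "project")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


_KNOWN_STAGES = ("simulate", "deg", "network", "phase-da", "annotate", "project")


def _build_simulation(raw: dict, errors: list[str]) -> SimulationConfig:
    plans_raw = raw.pop("module_plans", None)
    plans = None
    if plans_raw is not None:
        plans = []
        for i, p in enumerate(plans_raw):
            try:
                p = dict(p)
                if "loading_range" in p:
                    p["loading_range"] = tuple(p["loading_range"])
                plans.append(ModulePlan(**p))
            except (TypeError, ValueError) as exc:
                errors.append(f"simulation.module_plans[{i}]: {exc}")
    try:
        kwargs = dict(raw)
        if "timepoints" in kwargs:
            kwargs["timepoints"] = tuple(kwargs["timepoints"])
        if plans is not None:
            kwargs["module_plans"] = plans
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"simulation: {exc}")
        return SimulationConfig(module_plans=default_module_plans())


def _build(cls, raw: dict, section: str, errors: list[str]):
    try:
        if "candidate_powers" in raw:
            raw["candidate_powers"] = tuple(raw["candidate_powers"])
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return cls()


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; raises :class:`ConfigError` listing
    every violation with its field path.  ``path`` may be None (defaults
    only); ``overrides`` (e.g. CLI flags) take precedence."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError([f"config root must be a mapping, got {type(loaded).__name__}"])
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    errors: list[str] = []
    known = {"simulation", "network", "projection", "da_threshold", "seed",
             "outdir", "stages"}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key}")

    simulation = _build_simulation(dict(raw.get("simulation", {})), errors)
    network = _build(NetworkParams, dict(raw.get("network", {})), "network", errors)
    projection = _build(ProjectionParams, dict(raw.get("projection", {})),
                        "projection", errors)

    da_threshold = raw.get("da_threshold", 2.5)
    if not isinstance(da_threshold, (int, float)) or da_threshold <= 0:
        errors.append("da_threshold: must be a positive number")
        da_threshold = 2.5
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0
    stages = tuple(raw.get("stages", ("simulate", "deg", "network", "phase-da",
                                      "project")))
    for s in stages:
        if s not in _KNOWN_STAGES:
            errors.append(f"stages: unknown stage {s!r}")

    if errors:
        raise ConfigError(errors)
    sim = simulation
    if seed != sim.seed:
        sim.seed = seed
    return RunConfig(simulation=sim, network=network, projection=projection,
                     da_threshold=float(da_threshold), seed=seed,
                     outdir=str(raw.get("outdir", "fibromod_out")),
                     stages=stages)
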