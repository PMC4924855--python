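"""Config loading, validation and tabular (CSV) trajectory I/O."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .model import ModelParams, Trajectory, default_params, TRAJECTORY_COLUMNS
from .scenarios import InterventionProtocol, OnsetSchedule

__all__ = [
    "ConfigError",
    "ConfigParseError",
    "ConfigValidationError",
    "RunConfig",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_branch_diagram",
]

SCENARIOS = ("onset", "stationary", "intervention", "equilibria")


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigParseError(ConfigError):
    """The config file could not be parsed as YAML."""


class ConfigValidationError(ConfigError):
    """The config parsed but a value or key is invalid; names the offender."""


@dataclass(frozen=True)
class StationarySettings:
    E: float = 0.1525
    lam: float = 1.0


@dataclass(frozen=True)
class EquilibriaSettings:
    E_min: float = -0.6
    E_max: float = 0.35
    step: float = 0.005


@dataclass
class RunConfig:
    """A fully validated run request: parameters, scenario and its settings."""

    params: ModelParams = field(default_factory=default_params)
    scenario: str = "stationary"
    horizon: int = 520
    seed: int | None = None
    n_replicates: int = 50
    out: str | None = None
    onset: OnsetSchedule = field(default_factory=OnsetSchedule)
    stationary: StationarySettings = field(default_factory=StationarySettings)
    intervention: InterventionProtocol = field(default_factory=InterventionProtocol)
    equilibria: EquilibriaSettings = field(default_factory=EquilibriaSettings)


def _build_block(cls, raw: dict, block: str, defaults=None):
    """Instantiate a settings dataclass from a dict, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigValidationError(
            f"unknown key(s) {sorted(unknown)} in block '{block}' "
            f"(allowed: {sorted(allowed)})"
        )
    base = {f.name: getattr(defaults, f.name) for f in fields(cls)} if defaults else {}
    base.update(raw)
    try:
        return cls(**base)
    except (ValueError, TypeError) as exc:
        raise ConfigValidationError(f"invalid value in block '{block}': {exc}") from exc


_TOP_KEYS = {
    "params", "scenario", "horizon", "seed", "n_replicates", "out",
    "onset", "stationary", "intervention", "equilibria",
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys fail fast with the offending key named; every model
    invariant (``d`` in (0,1), ``b*q < 1``, ...) is checked at load time.
    Missing blocks fall back to the default parameter set and the standard
    scenario settings.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigParseError(f"config file {path} is not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigParseError(f"config file {path} must contain a mapping at top level")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigValidationError(
            f"unknown top-level key(s) {sorted(unknown)} (allowed: {sorted(_TOP_KEYS)})"
        )
    cfg = RunConfig()
    if "params" in raw:
        cfg.params = _build_block(ModelParams, raw["params"], "params", default_params())
    if "scenario" in raw:
        if raw["scenario"] not in SCENARIOS:
            raise ConfigValidationError(
                f"scenario must be one of {SCENARIOS}, got {raw['scenario']!r}"
            )
        cfg.scenario = raw["scenario"]
    if "horizon" in raw:
        if not isinstance(raw["horizon"], int) or raw["horizon"] < 1:
            raise ConfigValidationError(f"horizon must be a positive integer, got {raw['horizon']!r}")
        cfg.horizon = raw["horizon"]
    if "seed" in raw:
        if raw["seed"] is not None and not isinstance(raw["seed"], int):
            raise ConfigValidationError(f"seed must be an integer or null, got {raw['seed']!r}")
        cfg.seed = raw["seed"]
    if "n_replicates" in raw:
        if not isinstance(raw["n_replicates"], int) or raw["n_replicates"] < 1:
            raise ConfigValidationError(
                f"n_replicates must be a positive integer, got {raw['n_replicates']!r}"
            )
        cfg.n_replicates = raw["n_replicates"]
    if "out" in raw:
        cfg.out = raw["out"]
    if "onset" in raw:
        cfg.onset = _build_block(OnsetSchedule, raw["onset"], "onset", OnsetSchedule())
    if "stationary" in raw:
        cfg.stationary = _build_block(
            StationarySettings, raw["stationary"], "stationary", StationarySettings()
        )
    if "intervention" in raw:
        cfg.intervention = _build_block(
            InterventionProtocol, raw["intervention"], "intervention", InterventionProtocol()
        )
    if "equilibria" in raw:
        cfg.equilibria = _build_block(
            EquilibriaSettings, raw["equilibria"], "equilibria", EquilibriaSettings()
        )
    return cfg


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory as CSV (header ``t,C,S,E,lambda,R,A,V``)."""
    try:
        trajectory.to_frame().to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write trajectory to {path}: {exc}") from exc


def read_trajectory(path) -> pd.DataFrame:
    """Read a trajectory CSV back as a DataFrame with the canonical columns."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read trajectory from {path}: {exc}") from exc
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file {path} is missing column(s) {sorted(missing)}")
    return df[TRAJECTORY_COLUMNS]


def write_branch_diagram(diagram, path) -> None:
    """Write a branch diagram as CSV (E, C_star, S_star, regime, stable, eig1, eig2)."""
    try:
        diagram.to_frame().to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write branch diagram to {path}: {exc}") from exc
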