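"""Structured run configuration: strict YAML parsing and validation.

A run configuration names the experiment (``single`` | ``rotation`` |
``tissue``), the model parameter block, an optional cell-cycle block, the
environment (micropattern) block, and run control (MCS count, replicates,
lattice size, recorder interval).  Unknown keys anywhere are hard errors,
reported with their key path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .energetics import ModelParams
from .hexgrid import ConfigurationError
from .proliferation import CycleParams
from .presets import figure_preset

__all__ = ["RunParams", "RunConfig", "load_config", "config_from_dict", "from_preset"]

_EXPERIMENTS = ("single", "rotation", "tissue")

_MODEL_KEYS = {"kappa_A", "kappa_P", "eps0", "delta_eps", "R", "mu",
               "B", "delta_B", "D", "kBT", "phi_mode", "friction_mode"}
_CYCLE_KEYS = {"enabled", "Tg", "Td", "A_T", "A_ref", "stochastic_rate"}
_ENV_KEYS = {"pattern", "r0", "center", "x_left", "x_right", "t_remove", "phi_file"}
_RUN_KEYS = {"T_sim", "replicates", "seed", "record_every", "n_cols", "n_rows",
             "n_cells", "cell_area", "out_dir"}
_TOP_KEYS = {"experiment", "model", "cycle", "environment", "run"}


@dataclass
class RunParams:
    """Run control: duration, replication, lattice geometry, recording."""
    T_sim: int = 2000
    replicates: int = 1
    seed: int = 0
    record_every: int = 1
    n_cols: int = 96
    n_rows: int = 96
    n_cells: int | None = None
    cell_area: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.T_sim < 1:
            raise ConfigurationError("run.T_sim must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("run.replicates must be >= 1")
        if self.record_every < 1:
            raise ConfigurationError("run.record_every must be >= 1")


@dataclass
class RunConfig:
    """Fully validated configuration for one experiment."""
    experiment: str
    model: ModelParams
    run: RunParams = field(default_factory=RunParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    environment: dict = field(default_factory=lambda: {"pattern": "none"})

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ConfigurationError(
                f"experiment must be one of {_EXPERIMENTS}, got {self.experiment!r}")
        pat = self.environment.get("pattern", "none")
        if pat not in ("none", "circle", "strip", "raster"):
            raise ConfigurationError(f"environment.pattern: unknown pattern {pat!r}")
        if pat == "circle" and "r0" not in self.environment:
            raise ConfigurationError("environment: circle pattern requires r0")
        if pat == "strip":
            for k in ("x_left", "x_right"):
                if k not in self.environment:
                    raise ConfigurationError(f"environment: strip pattern requires {k}")

    def to_dict(self) -> dict:
        d = {
            "experiment": self.experiment,
            "model": asdict(self.model),
            "cycle": asdict(self.cycle),
            "environment": dict(self.environment),
            "run": asdict(self.run),
        }
        return d

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _check_keys(block: dict, allowed: set, path: str) -> None:
    for k in block:
        if k not in allowed:
            raise ConfigurationError(f"unknown key {path}.{k!r}")


def config_from_dict(raw: dict) -> RunConfig:
    """Validate a nested dict (the YAML/preset schema) into a RunConfig."""
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<top>")
    if "experiment" not in raw or "model" not in raw:
        raise ConfigurationError("configuration requires 'experiment' and 'model'")
    model_raw = dict(raw["model"])
    _check_keys(model_raw, _MODEL_KEYS, "model")
    cycle_raw = dict(raw.get("cycle", {}))
    _check_keys(cycle_raw, _CYCLE_KEYS, "cycle")
    env_raw = dict(raw.get("environment", {"pattern": "none"}))
    _check_keys(env_raw, _ENV_KEYS, "environment")
    run_raw = dict(raw.get("run", {}))
    _check_keys(run_raw, _RUN_KEYS, "run")
    return RunConfig(
        experiment=raw["experiment"],
        model=ModelParams(**model_raw),
        cycle=CycleParams(**cycle_raw),
        environment=env_raw,
        run=RunParams(**run_raw),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {p}: {exc}") from exc
    return config_from_dict(raw)


def from_preset(name: str, **overrides) -> RunConfig:
    """A bundled figure preset as a validated RunConfig.

    ``overrides`` are dotted-path scalar overrides, e.g.
    ``from_preset('fig2', **{'model.delta_eps': 30, 'run.T_sim': 500})``.
    """
    raw = figure_preset(name)
    for key, value in overrides.items():
        parts = key.split(".")
        node = raw
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return config_from_dict(raw)
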