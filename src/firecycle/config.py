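"""Run configuration: YAML file handling with fail-closed validation.

A configuration file holds any subset of the sections below; unspecified
keys fall back to the package defaults (the base-run parameter set). Unknown
keys are rejected so typos cannot silently revert a value to its default.

Example::

    params:
      delta1: 0.5
    policy:
      p1: true
      start_time: 5.0
    integrator:
      dt: 0.015625
      horizon: 20.0
    seed: 1
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .params import ModelParams, PolicyConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class IntegratorConfig:
    dt: float = 1.0 / 64.0
    horizon: float = 20.0
    method: str = "rk4"


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    params: ModelParams = field(default_factory=ModelParams)
    policy: PolicyConfig = field(default_factory=PolicyConfig)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params),
            "policy": dataclasses.asdict(self.policy),
            "integrator": dataclasses.asdict(self.integrator),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ConfigError) as exc:
        raise ConfigError(f"invalid '{section}' configuration: {exc}") from exc


def from_dict(data: dict) -> RunConfig:
    """Merge a (possibly partial) mapping over the defaults."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - {"params", "policy", "integrator", "seed", "output_dir"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    return RunConfig(
        params=_build_section(ModelParams, data.get("params") or {}, "params"),
        policy=_build_section(PolicyConfig, data.get("policy") or {}, "policy"),
        integrator=_build_section(IntegratorConfig, data.get("integrator") or {}, "integrator"),
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", ".")),
    )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` or an empty file gives defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective configuration next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
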