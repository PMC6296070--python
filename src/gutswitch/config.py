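"""Run configuration: validated YAML config with preset + override semantics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelParameters, PARAM_NAMES, VARIANTS, preset

__all__ = ["RunConfig", "load_config", "ConfigError"]

EXPERIMENTS = ("simulate", "equilibria", "continue", "transform", "verify", "reproduce")


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


_TOP_KEYS = {
    "experiment",
    "variant",
    "preset",
    "overrides",
    "protocol",
    "range",
    "density",
    "seed",
    "out",
}


@dataclass
class RunConfig:
    """Validated configuration for one analysis run.

    ``overrides`` are applied on top of the named parameter preset;
    unknown keys anywhere raise :class:`ConfigError` naming the key.
    The seed only feeds Monte-Carlo checks — equilibria, branches and
    folds are deterministic.
    """

    experiment: str = "equilibria"
    variant: str = "core"
    preset_name: str = "fig2a"
    overrides: dict[str, float] = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    range_block: dict = field(default_factory=dict)
    density: dict = field(default_factory=dict)
    seed: int = 0
    out: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        unknown = set(self.overrides) - set(PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown parameter override(s): {sorted(unknown)}")
        try:
            self.params  # triggers ModelParameters validation
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    @property
    def params(self) -> ModelParameters:
        return preset(self.preset_name).with_(**self.overrides)

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "variant": self.variant,
            "preset": self.preset_name,
            "overrides": dict(self.overrides),
            "protocol": dict(self.protocol),
            "range": dict(self.range_block),
            "density": dict(self.density),
            "seed": self.seed,
            "out": self.out,
        }

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    overrides = raw.get("overrides") or {}
    if not isinstance(overrides, dict):
        raise ConfigError("overrides must be a mapping of parameter name -> value")
    return RunConfig(
        experiment=raw.get("experiment", "equilibria"),
        variant=raw.get("variant", "core"),
        preset_name=raw.get("preset", "fig2a"),
        overrides={str(k): float(v) for k, v in overrides.items()},
        protocol=raw.get("protocol") or {},
        range_block=raw.get("range") or {},
        density=raw.get("density") or {},
        seed=int(raw.get("seed", 0)),
        out=raw.get("out"),
    )


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
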