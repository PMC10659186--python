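"""Run configuration: defaults < config file < command-line overrides."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .counting import CountingParams
from .model import ModelConfig, TrainConfig
from .preprocess import AugmentSpec, FrameSpec
from .synthetic import SimConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Unknown key or ill-typed value in a configuration source."""


@dataclass(frozen=True)
class RunConfig:
    """Merged settings for every pipeline stage plus global controls."""

    sim: SimConfig = field(default_factory=SimConfig)
    frame: FrameSpec = field(default_factory=FrameSpec)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    counting: CountingParams = field(default_factory=CountingParams)
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."


_SECTION_TYPES = {
    "sim": SimConfig,
    "frame": FrameSpec,
    "augment": AugmentSpec,
    "model": ModelConfig,
    "train": TrainConfig,
    "counting": CountingParams,
}
_SCALAR_KEYS = {"seed", "log_level", "out_dir"}


def _coerce(value: Any, target_type: Any) -> Any:
    if target_type in (tuple,) or str(target_type).startswith("tuple"):
        return tuple(value) if isinstance(value, (list, tuple)) else value
    return value


def _build_section(cls: type, base: Any, updates: dict[str, Any], section: str) -> Any:
    valid = {f.name: f for f in fields(cls)}
    for key, value in updates.items():
        if key not in valid:
            raise ConfigError(f"unknown key {section}.{key!r}")
    kwargs = {key: _coerce(value, valid[key].type) for key, value in updates.items()}
    try:
        return dataclasses.replace(base, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def _merge(config: RunConfig, data: dict[str, Any], source: str) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    updates: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"{source}: section {key!r} must be a mapping")
            updates[key] = _build_section(
                _SECTION_TYPES[key], getattr(config, key), value, key
            )
        elif key in _SCALAR_KEYS:
            expected = int if key == "seed" else str
            if not isinstance(value, expected):
                raise ConfigError(
                    f"{source}: key {key!r} expects {expected.__name__}, got {value!r}"
                )
            updates[key] = value
        else:
            raise ConfigError(f"{source}: unknown key {key!r}")
    return dataclasses.replace(config, **updates)


def load_config(
    path: str | Path | None = None, overrides: dict[str, Any] | None = None
) -> RunConfig:
    """Resolve the run configuration.

    ``overrides`` uses dotted keys (e.g. ``counting.prob_threshold``) and
    wins over the file, which wins over built-in defaults. Unknown keys are
    rejected, naming the offender.
    """
    config = RunConfig()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        config = _merge(config, data, str(path))
    if overrides:
        nested: dict[str, Any] = {}
        for dotted, value in overrides.items():
            parts = dotted.split(".")
            if len(parts) == 1:
                nested[parts[0]] = value
            elif len(parts) == 2:
                nested.setdefault(parts[0], {})[parts[1]] = value
            else:
                raise ConfigError(f"override key too deep: {dotted!r}")
        config = _merge(config, nested, "overrides")
    logger.info("resolved configuration: %s", config)
    return config
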