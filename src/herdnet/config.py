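"""Run configuration: defaults <- config file (YAML/JSON) <- CLI flags."""
from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .experiments import DEFAULT_CAPACITIES, DEFAULT_PROBS
from .params import ConfigurationError, SimParams

__all__ = ["RunConfig", "load_config", "ConfigurationError"]

_BOOL_FIELDS = {
    "uniform_intensity",
    "enable_networks",
    "enable_deaths",
    "enable_global_disasters",
}
_INT_FIELDS = {"n_households", "n_steps", "seed", "n_runs", "base_seed", "trigger_size"}
_GRID_FIELDS = {"capacities", "probs"}


@dataclass(frozen=True)
class RunConfig:
    """Everything a command-line experiment needs: the model parameters plus
    batch settings, sweep grids and output location."""

    params: SimParams = field(default_factory=SimParams)
    n_runs: int = 100
    base_seed: int = 0
    capacities: tuple[float, ...] = DEFAULT_CAPACITIES
    probs: tuple[float, ...] = DEFAULT_PROBS
    low_capacity: float = 10_000.0
    high_capacity: float = 50_000.0
    trigger_size: int = 20
    out_dir: str = "results"

    def validate(self) -> None:
        self.params.validate()
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        if len(self.capacities) == 0 or len(self.probs) == 0:
            raise ConfigurationError("capacities and probs must be non-empty")
        for prob in self.probs:
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError("probs entries must lie in [0, 1]")
        for cap in self.capacities:
            if cap < 0:
                raise ConfigurationError("capacities entries must be non-negative")
        if not self.low_capacity < self.high_capacity:
            raise ConfigurationError("low_capacity must be below high_capacity")
        if self.trigger_size < 1:
            raise ConfigurationError("trigger_size must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        out = self.params.to_dict()
        out.update(
            n_runs=self.n_runs,
            base_seed=self.base_seed,
            capacities=list(self.capacities),
            probs=list(self.probs),
            low_capacity=self.low_capacity,
            high_capacity=self.high_capacity,
            trigger_size=self.trigger_size,
            out_dir=self.out_dir,
        )
        return out


_PARAM_KEYS = {f.name for f in fields(SimParams)}
_CONFIG_KEYS = {
    "n_runs",
    "base_seed",
    "capacities",
    "probs",
    "low_capacity",
    "high_capacity",
    "trigger_size",
    "out_dir",
}


def _coerce(key: str, value: Any) -> Any:
    try:
        if key in _GRID_FIELDS:
            if not isinstance(value, (list, tuple)):
                raise TypeError("expected a list")
            return tuple(float(v) for v in value)
        if key in _BOOL_FIELDS:
            if isinstance(value, bool):
                return value
            if isinstance(value, str):
                low = value.strip().lower()
                if low in {"true", "yes", "on", "1"}:
                    return True
                if low in {"false", "no", "off", "0"}:
                    return False
            raise TypeError("expected a boolean")
        if key in _INT_FIELDS:
            if value is None and key == "seed":
                return None
            if isinstance(value, bool) or (
                isinstance(value, float) and not value.is_integer()
            ):
                raise TypeError("expected an integer")
            return int(value)
        if key == "out_dir":
            return str(value)
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(
            f"configuration key {key!r}: cannot interpret {value!r} ({exc})"
        ) from None


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Build a validated RunConfig from defaults, an optional YAML/JSON file
    and CLI-style overrides, in increasing precedence.

    Unknown keys are rejected by name; ``None`` override values (unset CLI
    flags) are ignored.
    """
    merged: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text) or {}
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must map keys to values")
        merged.update(data)
    for key, value in (overrides or {}).items():
        if value is not None:
            merged[key] = value

    unknown = set(merged) - _PARAM_KEYS - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}"
        )

    param_kwargs = {
        k: _coerce(k, v) for k, v in merged.items() if k in _PARAM_KEYS
    }
    config_kwargs = {
        k: _coerce(k, v) for k, v in merged.items() if k in _CONFIG_KEYS
    }
    try:
        config = RunConfig(params=SimParams(**param_kwargs), **config_kwargs)
        config.validate()
    except ConfigurationError:
        raise
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from None
    return config
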