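"""Model parameters for the pastoral household simulation.

All animal quantities are non-negative reals (the model does not round herds
to whole animals). Thresholds are compared strictly, matching the rules
"herd < 60", "herd > 800", "herd < 500" and "herd < 2".
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class SimParams:
    """Constants, variant flags and run-length settings for one simulation.

    Defaults are the standard study conditions: 100 households starting with
    60 animals each, 10% herd growth per step, individual disasters removing
    50% of a herd, poverty/patron/floor thresholds of 60/800/500 animals, a
    60-animal patron-to-client transfer, death below 2 animals, and 2,000
    time steps. Carrying capacity defaults to 10,000 animals and the disaster
    probability to 10% per household per step; experiments sweep both.
    """

    n_households: int = 100
    initial_herd: float = 60.0
    growth_rate: float = 0.10
    disaster_prob: float = 0.10
    disaster_intensity: float = 0.50
    uniform_intensity: bool = False
    carrying_capacity: float = 10_000.0
    poverty_threshold: float = 60.0
    patron_threshold: float = 800.0
    patron_floor: float = 500.0
    transfer_amount: float = 60.0
    death_threshold: float = 2.0
    n_steps: int = 2_000
    enable_networks: bool = True
    enable_deaths: bool = True
    enable_global_disasters: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_households < 1:
            raise ConfigurationError("n_households must be >= 1")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        for name in (
            "initial_herd",
            "carrying_capacity",
            "poverty_threshold",
            "patron_threshold",
            "patron_floor",
            "transfer_amount",
            "death_threshold",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.disaster_prob <= 1.0:
            raise ConfigurationError("disaster_prob must lie in [0, 1]")
        if not 0.0 <= self.disaster_intensity <= 1.0:
            raise ConfigurationError("disaster_intensity must lie in [0, 1]")
        if self.growth_rate <= 0.0:
            raise ConfigurationError("growth_rate must be positive")
        if not (
            self.death_threshold
            < self.poverty_threshold
            < self.patron_floor
            < self.patron_threshold
        ):
            raise ConfigurationError(
                "thresholds must satisfy death < poverty < patron_floor "
                "< patron_threshold"
            )

    def replace(self, **changes: Any) -> "SimParams":
        """Return a copy with ``changes`` applied (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# Variant used for the baseline inequality experiment: households grow and
# suffer disasters but never interact or die, so the final Gini index
# measures inequality before any redistribution masks it.
def inequality_variant(params: SimParams) -> SimParams:
    return params.replace(enable_networks=False, enable_deaths=False)
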