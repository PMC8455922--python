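"""Run configuration shared by the model pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    log_base: float = 10.0
    threshold_r: Optional[float] = None  # None -> use the scenario's r
    alpha: float = 0.5
    beta: float = 0.5
    extension_depth: int = 3
    extension_cap: int = 10**5
    typicality_variant: str = "raw"  # "raw" | "normalized"
    tolerance: float = 0.005
    seed: Optional[int] = None

    def __post_init__(self):
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ConfigError(f"alpha + beta = {self.alpha + self.beta}, expected 1")
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("alpha and beta must be nonnegative")
        if self.log_base <= 1.0:
            raise ConfigError("log base must exceed 1")
        if self.threshold_r is not None and not (0.0 <= self.threshold_r < 1.0):
            raise ConfigError("threshold r must lie in [0, 1)")
        if self.typicality_variant not in ("raw", "normalized"):
            raise ConfigError(f"unknown typicality variant {self.typicality_variant!r}")
        if self.extension_depth < 1:
            raise ConfigError("extension depth must be >= 1")
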