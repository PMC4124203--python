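"""Run configuration: loading, validation and echoing.

A run is described by a flat key-value file (TOML or JSON) whose defaults
are the reference protocol: a 20d x 20d periodic box filled to reduced
density 0.3 at T* = 1.0 with a lambda = 1.5 triangular well, 3000 attempted
moves per particle capped at 0.5d per axis, 100 realizations, and an
equal-thirds R1 | R2 | R3 stripe pattern with factors U1, U2, U1.  Command
line flags override file values, and every output directory receives a JSON
echo of the effective configuration that reloads to an identical RunConfig.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .engine import SimulationParams
from .geometry import Box, RegionPattern
from .potential import PotentialParams

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]

# RSA of aligned hard disks jams near area fraction 0.547; rho* pi/4 above
# that is very unlikely to complete.
_RSA_JAMMING_DENSITY = 0.547 * 4 / np.pi


class ConfigError(ValueError):
    """Raised with the full list of validation problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass
class RunConfig:
    """Complete, validated parameter set for a simulation + analysis run."""

    side_length: float = 20.0
    target_density: float = 0.3
    reduced_temperature: float = 1.0
    lambda_factor: float = 1.5
    u1: float = 1.0
    u2: float = 1.0
    pattern: list | None = None  # (label, width-fraction, factor) triples
    move_budget: int = 3000
    max_displacement: float = 0.5
    insertion_retry_cap: int = 1_000_000
    realizations: int = 100
    seed: int = 0
    dr: float = 0.05
    r_max: float | None = None
    out_dir: str = "sqsim_out"

    def validate(self) -> None:
        problems: list[str] = []
        if self.side_length <= 0:
            problems.append(f"side_length must be positive, got {self.side_length}")
        if self.lambda_factor <= 1:
            problems.append(f"lambda_factor must exceed 1, got {self.lambda_factor}")
        if self.side_length > 0 and self.side_length <= 2 * self.lambda_factor:
            problems.append(
                f"side_length {self.side_length} must exceed twice the "
                f"interaction range {self.lambda_factor}"
            )
        if self.target_density <= 0:
            problems.append(f"target_density must be positive, got {self.target_density}")
        if self.reduced_temperature <= 0:
            problems.append(
                f"reduced_temperature must be positive, got {self.reduced_temperature}"
            )
        for name in ("u1", "u2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                problems.append(f"{name} must be strictly positive and finite, got {v}")
        if self.move_budget < 0:
            problems.append(f"move_budget must be non-negative, got {self.move_budget}")
        if self.max_displacement <= 0 or self.max_displacement > self.side_length / 2:
            problems.append(
                f"max_displacement must lie in (0, L/2], got {self.max_displacement}"
            )
        if self.insertion_retry_cap < 1:
            problems.append("insertion_retry_cap must be at least 1")
        if self.realizations < 1:
            problems.append(f"realizations must be at least 1, got {self.realizations}")
        if self.dr <= 0:
            problems.append(f"dr must be positive, got {self.dr}")
        if self.r_max is not None and not 0 < self.r_max <= self.side_length / 2:
            problems.append(f"r_max must lie in (0, L/2], got {self.r_max}")
        if self.pattern is not None:
            try:
                self.region_pattern()
            except Exception as err:  # surface the pattern's own message
                problems.append(f"pattern: {err}")
        if problems:
            raise ConfigError(problems)
        if self.target_density > _RSA_JAMMING_DENSITY:
            warnings.warn(
                f"target_density {self.target_density} exceeds the hard-disk "
                f"RSA jamming density ~{_RSA_JAMMING_DENSITY:.3f}; insertion "
                "may exhaust its retry cap",
                stacklevel=2,
            )

    # --- constructors for the domain objects ---

    def box(self) -> Box:
        return Box(side_length=self.side_length)

    def region_pattern(self) -> RegionPattern:
        if self.pattern is None:
            return RegionPattern.equal_thirds(self.u1, self.u2)
        labels, fracs, factors = zip(*[(str(t[0]), float(t[1]), float(t[2])) for t in self.pattern])
        return RegionPattern(labels, fracs, factors)

    def potential_params(self) -> PotentialParams:
        return PotentialParams(
            lambda_factor=self.lambda_factor,
            reduced_temperature=self.reduced_temperature,
        )

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            target_density=self.target_density,
            move_budget=self.move_budget,
            max_displacement=self.max_displacement,
            insertion_retry_cap=self.insertion_retry_cap,
            realizations=self.realizations,
            seed=self.seed,
        )

    def effective_r_max(self) -> float:
        return self.side_length / 2 if self.r_max is None else self.r_max

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["pattern"] is not None:
            d["pattern"] = [list(t) for t in d["pattern"]]
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}
_INT_FIELDS = {"move_budget", "insertion_retry_cap", "realizations", "seed"}


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Build a validated RunConfig from an optional file plus overrides.

    The file may be TOML or JSON (by extension).  Unknown keys are rejected;
    all validation problems are reported together.  An empty file yields the
    full default parameter set.
    """
    data: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError([f"config file not found: {path}"])
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text() or "{}")
        else:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = sorted(set(data) - _FIELD_NAMES)
    if unknown:
        raise ConfigError([f"unknown configuration key: {k}" for k in unknown])

    problems: list[str] = []
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _INT_FIELDS:
            if value is not None and (isinstance(value, bool) or int(value) != value):
                problems.append(f"{key} must be an integer, got {value!r}")
                continue
            value = None if value is None else int(value)
        kwargs[key] = value
    if problems:
        raise ConfigError(problems)

    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a JSON echo of the effective configuration (reloadable)."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
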