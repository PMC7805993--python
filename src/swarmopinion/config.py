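"""Run configuration for the density-classification swarm scenario.

The scenario has a small, fixed parameter surface: swarm size, the unit
square, one radius serving both collision avoidance and opinion perception,
a constant per-step speed, the misperception probability ``gamma``, the
odd memory size that triggers opinion revisions, and run-length /
repetition counts.  Defaults are the reference values used throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class SwarmConfig:
    """Parameters of the density-classification scenario.

    Attributes
    ----------
    n_agents:
        Swarm size ``N``.
    world_side:
        Side length of the square arena (dimensionless, 1.0).
    radius:
        Collision-avoidance radius, equal to the mutual perception range.
    speed:
        Displacement per iteration; constant for every agent at all times.
    gamma:
        Probability that an agent misperceives (flips) the opinion of an
        encountered agent.  ``1 - gamma`` is the recognition accuracy.
    memory_size:
        Number of perceived opinions collected before an agent revises its
        opinion to the majority of its memory.  Must be odd so a strict
        majority always exists.
    n_iterations:
        Iterations per simulation run.
    n_repetitions:
        Number of independent runs in an ensemble.
    initial_fraction_a:
        Fraction of agents initialised with opinion A (exact quota).
    seed:
        Root seed for the run or ensemble.
    """

    n_agents: int = 150
    world_side: float = 1.0
    radius: float = 0.01
    speed: float = 0.01
    gamma: float = 0.2
    memory_size: int = 5
    n_iterations: int = 8000
    n_repetitions: int = 1
    initial_fraction_a: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be at least 2")
        if self.world_side <= 0:
            raise ValueError("world_side must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.memory_size < 1 or self.memory_size % 2 == 0:
            raise ValueError("memory_size must be odd and >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if not 0.0 <= self.initial_fraction_a <= 1.0:
            raise ValueError("initial_fraction_a must lie in [0, 1]")

    def replace(self, **changes) -> "SwarmConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> SwarmConfig:
    """Load a :class:`SwarmConfig` from a YAML file.

    Missing keys take the scenario defaults; unknown keys are rejected with
    a field-level message.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(SwarmConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
    try:
        return SwarmConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def save_config(config: SwarmConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` inverts this exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
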