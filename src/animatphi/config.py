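"""Experiment configuration: dataclasses, YAML round-trip, config hashing.

Two built-in profiles:

* ``paper_profile`` -- the published study conditions: 64x64 world, spawn
  distance 32, 512-step lifetimes, populations of 100 evolved for 200,000
  generations in 200 replicates, fitness over all 24 action mappings.
* ``desk_profile`` -- a scaled-down profile preserving the structure at
  single-workstation cost: 16x16 world, spawn distance 8 (the same half-
  width ratio), 256-step lifetimes, populations of 50 for 2,000 generations,
  10 replicates, fitness on 6 mappings resampled each generation (the full
  24 for final evaluation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .genome import MutationRates


@dataclass
class WorldConfig:
    width: int = 64
    height: int = 64
    obstacle_fraction: float = 0.05
    spawn_distance: int = 32


@dataclass
class PhiConfig:
    """Parameters of the integrated-information measurements."""

    node_set: str = "all"            # "all" | "exclude_sensors"
    samples_per_state: int = 64      # sampled-TPM draws per start state
    analytic_max_nodes: int = 12     # exact TPM only below these bounds
    analytic_max_output_bits: int = 20
    checkpoint_stride: int = 50      # lifetime timesteps between TPM snapshots


@dataclass
class ExperimentConfig:
    profile: str = "paper"
    world: WorldConfig = field(default_factory=WorldConfig)
    phi: PhiConfig = field(default_factory=PhiConfig)
    mutation: MutationRates = field(default_factory=MutationRates)
    lifetime: int = 512
    population_size: int = 100
    generations: int = 200_000
    replicates: int = 200
    tournament_size: int = 2
    genome_length: int = 5_000
    n_seed_codons: int = 4
    fitness_mappings: int | None = None  # None = all 24
    seed: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["world"] = WorldConfig(**d.get("world", {}))
        d["phi"] = PhiConfig(**d.get("phi", {}))
        d["mutation"] = MutationRates(**d.get("mutation", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        """Stable hash stamped into every output artifact."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def paper_profile(seed: int = 1) -> ExperimentConfig:
    return ExperimentConfig(seed=seed)


def desk_profile(seed: int = 1, generations: int = 2_000,
                 replicates: int = 10) -> ExperimentConfig:
    return ExperimentConfig(
        profile="desk",
        world=WorldConfig(width=16, height=16, obstacle_fraction=0.05,
                          spawn_distance=8),
        phi=PhiConfig(checkpoint_stride=25),
        lifetime=256,
        population_size=50,
        generations=generations,
        replicates=replicates,
        fitness_mappings=6,
        seed=seed,
    )
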