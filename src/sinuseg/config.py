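"""Run configuration: one YAML-serializable object tying together the
phantom, network, training and pipeline parameter blocks plus the global
seed, so any run is reproducible from its logged config alone.

Unknown keys are rejected on load (typos fail loudly instead of being
silently ignored). The global seed fans out to per-component seeds via a
fixed :class:`numpy.random.SeedSequence` derivation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import ConfigError
from .phantoms import JitterSpec, PhantomSpec
from .pipeline import PipelineConfig
from .training import TrainConfig
from .unet3d import NetworkSpec

__all__ = ["RunConfig", "derive_seeds"]


def _build(cls, d: dict | None):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    if d is None:
        return cls()
    if not isinstance(d, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {type(d).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    # tuples arrive as lists from YAML
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    jitter: JitterSpec = field(default_factory=JitterSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0
    log_level: str = "INFO"

    _TOP = ("phantom", "jitter", "network", "train", "pipeline", "seed", "log_level")

    def to_dict(self) -> dict:
        return {
            "phantom": asdict(self.phantom),
            "jitter": asdict(self.jitter),
            "network": asdict(self.network),
            "train": asdict(self.train),
            "pipeline": asdict(self.pipeline),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls._TOP)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            phantom=PhantomSpec.from_dict(d["phantom"]) if "phantom" in d else PhantomSpec(),
            jitter=_build(JitterSpec, d.get("jitter")),
            network=_build(NetworkSpec, d.get("network")),
            train=_build(TrainConfig, d.get("train")),
            pipeline=_build(PipelineConfig, d.get("pipeline")),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def derive_seeds(seed: int, n: int = 8) -> list[int]:
    """Fan one global seed out to per-component seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]
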