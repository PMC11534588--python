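"""YAML-backed run configuration: every pipeline stage's parameters
round-trip through serialization unchanged."""

from __future__ import annotations

import dataclasses

import numpy as np
import yaml

from .degrade import SliceProfile
from .losses import LossConfig
from .models import ModelConfig
from .patches import ExtractionSpec
from .phantom import PhantomSpec
from .reconstruct import FusionSpec
from .train import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config", "derive_seed"]

_SECTIONS = {
    "phantom": PhantomSpec,
    "profile": SliceProfile,
    "extraction": ExtractionSpec,
    "model": ModelConfig,
    "loss": LossConfig,
    "train": TrainConfig,
    "fusion": FusionSpec,
}

#: fixed per-stage offsets for fanning one global seed out to stages
_STAGE_OFFSETS = {"phantom": 1, "extract": 2, "train": 3, "model": 4}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_OFFSETS.get(stage, 0)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    verbosity: int = 1
    phantom: PhantomSpec = dataclasses.field(default_factory=PhantomSpec)
    profile: SliceProfile = dataclasses.field(default_factory=SliceProfile)
    extraction: ExtractionSpec = dataclasses.field(default_factory=ExtractionSpec)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    fusion: FusionSpec = dataclasses.field(default_factory=FusionSpec)

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "verbosity": self.verbosity}
        for name in _SECTIONS:
            section = getattr(self, name)
            d = {}
            for f in dataclasses.fields(section):
                v = getattr(section, f.name)
                if f.name == "provider":     # injected object, not serializable
                    continue
                if isinstance(v, tuple):
                    v = list(v)
                d[f.name] = v
            out[name] = d
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for key in ("seed", "verbosity"):
            if key in d:
                kwargs[key] = d[key]
        for name, typ in _SECTIONS.items():
            if name in d:
                sect = dict(d[name])
                for k, v in sect.items():
                    if isinstance(v, list):
                        sect[k] = tuple(v)
                kwargs[name] = typ(**sect)
        return cls(**kwargs)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(path: str, cfg: RunConfig):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
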