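"""Run configuration: one serializable mapping covering every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ModelSpec, TrainConfig
from .synth import SynthConfig


@dataclass
class RunConfig:
    """Stage parameters for a reproducible end-to-end run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    ratio: int = 10
    n_af_bins: int = 100
    holdout_fraction: float = 0.2
    scan_window: int = 1000
    scan_rate: float = 0.05
    scan_coverage: float = 0.95
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("synth", SynthConfig), ("model", ModelSpec), ("train", TrainConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
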