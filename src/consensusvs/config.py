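"""Run configuration: a single YAML file with explicit seeds everywhere.

The config round-trips losslessly through YAML so a run can be reproduced
from its manifest alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class SimulateConfig:
    n_actives: int = 40
    n_decoys: int = 500
    channel_noise: float = 1.0
    activity_noise_sd: float = 0.1


@dataclass
class SplitConfig:
    train_frac: float = 0.7
    external_n: int = 10
    seed: int = 11


@dataclass
class ChannelConfig:
    similarity_k: int = 3
    pharmacophore_k: int = 4
    min_features: int = 4
    cluster_seed: int = 13
    docking_scores: str | None = None  # CSV / Vina log dir; None = synthetic table


@dataclass
class ModelConfig:
    models: list[str] | None = None  # None = all twelve
    selector: str = "mutual_information"
    selector_sizes: list[int] = field(default_factory=lambda: [10, 25, 50])
    feature_blocks: list[str] = field(default_factory=lambda: ["ecfp4", "descriptors"])
    mode: str = "wnew"
    cv_folds: int = 5
    split_seed: int = 17
    grid_seed: int = 19
    decoy_score_mode: str = "predictions"  # or "raw"


@dataclass
class EnrichConfig:
    ef_fractions: list[float] = field(default_factory=lambda: [0.01, 0.05])
    decoy_fractions: list[float] = field(default_factory=lambda: [0.01])
    bedroc_alpha: float = 20.0


@dataclass
class BiasConfig:
    percentile: float = 10.0


@dataclass
class RunConfig:
    seed: int = 0
    actives_csv: str | None = None  # None = use the synthetic generator
    decoys_csv: str | None = None
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    channels: ChannelConfig = field(default_factory=ChannelConfig)
    models: ModelConfig = field(default_factory=ModelConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    bias: BiasConfig = field(default_factory=BiasConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {"simulate": SimulateConfig, "split": SplitConfig,
                    "channels": ChannelConfig, "models": ModelConfig,
                    "enrich": EnrichConfig, "bias": BiasConfig}
        kwargs: dict = {}
        for key, value in data.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                known = sections[key].__dataclass_fields__
                bad = set(value) - set(known)
                if bad:
                    raise ConfigError(f"unknown option(s) in {key!r}: {sorted(bad)}")
                kwargs[key] = sections[key](**value)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown config field {key!r}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())
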