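"""Run configuration: faithful defaults, YAML files, CLI overrides.

Precedence is CLI flag > config file > built-in default, field by
field. Defaults encode the study protocol: threshold T = 210, 256-px
non-overlapping tiles, batch size 8, at most 50 epochs, early-stopping
patience 5.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class ThresholdSection:
    T: int = 210
    polarity: str = "dark_is_tissue"


@dataclass
class TilingSection:
    tile_size: int = 256
    stride: int | None = None          # None -> tile_size (non-overlapping)
    min_fg: float = 0.1
    downsample: int = 1


@dataclass
class SynthSection:
    n_slides: int = 20
    width_px: int = 512
    height_px: int = 512
    background_intensity: int = 240


@dataclass
class SplitSection:
    fractions: tuple[float, float, float] = (0.81, 0.09, 0.10)
    unit: str = "by_slide"


@dataclass
class ArchSection:
    backbone: str = "ensemble"         # or one of the five backbone names
    width: float = 1.0


@dataclass
class TrainSection:
    batch_size: int = 8
    max_epochs: int = 50
    early_stop_patience: int = 5
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    loss: str = "cross_entropy"


@dataclass
class MetricsSection:
    aggregation: str = "micro"
    spacing: float | None = None


@dataclass
class OverlaySection:
    blend_alpha: float = 0.5


@dataclass
class RunConfig:
    threshold: ThresholdSection = field(default_factory=ThresholdSection)
    tiling: TilingSection = field(default_factory=TilingSection)
    synth: SynthSection = field(default_factory=SynthSection)
    split: SplitSection = field(default_factory=SplitSection)
    arch: ArchSection = field(default_factory=ArchSection)
    train: TrainSection = field(default_factory=TrainSection)
    metrics: MetricsSection = field(default_factory=MetricsSection)
    overlay: OverlaySection = field(default_factory=OverlaySection)
    seed: int = 0
    workdir: str = "wsiseg_run"

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split"]["fractions"] = list(d["split"]["fractions"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        cfg.apply(data)
        return cfg

    def apply(self, overrides: dict) -> "RunConfig":
        """Deep-merge a nested (or dotted-key) override dict in place."""
        for key, value in overrides.items():
            if value is None:
                continue
            if "." in key:
                section, leaf = key.split(".", 1)
                self.apply({section: {leaf: value}})
                continue
            current = getattr(self, key, _MISSING)
            if current is _MISSING:
                raise ValueError(f"unknown config field {key!r}")
            if dataclasses.is_dataclass(current):
                if not isinstance(value, dict):
                    raise ValueError(f"config section {key!r} needs a mapping")
                for leaf, v in value.items():
                    if v is None:
                        continue
                    if not hasattr(current, leaf):
                        raise ValueError(
                            f"unknown config field {key}.{leaf!r}")
                    if leaf == "fractions":
                        v = tuple(float(x) for x in v)
                    setattr(current, leaf, v)
            else:
                setattr(self, key, value)
        return self

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


_MISSING = object()


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file, and
    optional (dotted-key) overrides, in increasing precedence."""
    cfg = RunConfig()
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg.apply(data)
    if overrides:
        cfg.apply(overrides)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha1(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
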