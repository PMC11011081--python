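"""Run configuration: one YAML file drives the whole pipeline.

The configuration serializes losslessly (round-trip tested) and rejects
unknown keys so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .data_pipeline import CLASS_NAMES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    data_root: str = "data"
    run_dir: str = "runs/default"
    head_variant: str = "pbatn"  # or "pban" (no shift, GRU head)
    backbone_preset: str = "tiny"  # "tiny" | "full" | "custom"
    backbone: dict = field(default_factory=dict)  # overrides / custom config
    dropout: float = 0.5
    gru_hidden: int = 512
    epochs: int = 20
    batch_size: int = 8
    optimizer: str = "adam"  # or "sgd"
    lr: float = 1e-3
    momentum: float = 0.9  # SGD only
    target_size: int = 64
    num_segments: int = 8
    test_fraction: float = 0.1
    train_val_ratio: float = 4.0
    seed: int = 0
    class_names: list = field(default_factory=lambda: list(CLASS_NAMES))

    def __post_init__(self):
        if self.head_variant not in ("pbatn", "pban"):
            raise ValueError(f"head_variant must be pbatn or pban, got {self.head_variant!r}")
        if self.backbone_preset not in ("tiny", "full", "custom"):
            raise ValueError(
                f"backbone_preset must be tiny, full or custom, got {self.backbone_preset!r}"
            )

    def backbone_config(self) -> BackboneConfig:
        if self.backbone_preset == "tiny":
            base = BackboneConfig.tiny().to_dict()
        elif self.backbone_preset == "full":
            base = BackboneConfig().to_dict()
        else:
            base = BackboneConfig().to_dict()
        base.update(self.backbone)
        base["input_frames"] = self.num_segments
        return BackboneConfig.from_dict(base)

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
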