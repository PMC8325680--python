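"""Run configuration: YAML file + flag overrides, snapshot on every run."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import FusionConfig, TrainConfig
from .pipeline import ExtractConfig


@dataclass
class RunConfig:
    extract: ExtractConfig = field(default_factory=ExtractConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    backbone: str = "stub"
    seed: int = 0
    log_level: str = "INFO"
    canvas_size: int = 256

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        cfg = cls(
            extract=ExtractConfig(**{**data.get("extract", {})}),
            fusion=FusionConfig(**{
                k: tuple(v) if k == "stream_kinds" else v
                for k, v in data.get("fusion", {}).items()}),
            train=TrainConfig(**{**data.get("train", {})}),
            backbone=data.get("backbone", "stub"),
            seed=data.get("seed", 0),
            log_level=data.get("log_level", "INFO"),
            canvas_size=data.get("canvas_size", 256),
        )
        for k, v in overrides.items():
            if v is None:
                continue
            if hasattr(cfg, k):
                setattr(cfg, k, v)
        return cfg

    def snapshot(self, out_dir) -> Path:
        """Write the fully resolved configuration next to the outputs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "resolved_config.yaml"
        d = {
            "extract": asdict(self.extract),
            "fusion": asdict(self.fusion),
            "train": asdict(self.train),
            "backbone": self.backbone,
            "seed": self.seed,
            "log_level": self.log_level,
            "canvas_size": self.canvas_size,
        }
        d["fusion"]["stream_kinds"] = list(d["fusion"]["stream_kinds"])
        d["extract"]["vein_scales"] = list(d["extract"]["vein_scales"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)
        return path
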