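"""Run configuration: one YAML file covering the phantom generator,
preprocessing, model architecture and training recipe.

Every run writes its fully resolved config next to its outputs so results
are reproducible from the file alone.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .io_preprocess import PreprocessSpec
from .model import SAFNetConfig
from .phantom import PhantomConfig
from .train_eval import AugmentParams, TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1

_TUPLE_FIELDS = {
    "shape", "target_shape", "input_shape", "aspp_dilations",
    "fusion_dilations", "intensity_means",
}


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
            for k, v in d.items()}


class RunConfig:
    """Bundle of the four section configs."""

    def __init__(self,
                 phantom: PhantomConfig | None = None,
                 preprocess: PreprocessSpec | None = None,
                 model: SAFNetConfig | None = None,
                 train: TrainConfig | None = None):
        self.phantom = phantom or PhantomConfig()
        self.preprocess = preprocess or PreprocessSpec()
        self.model = model or SAFNetConfig()
        self.train = train or TrainConfig()

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "phantom": asdict(self.phantom),
            "preprocess": asdict(self.preprocess),
            "model": asdict(self.model),
            "train": asdict(self.train),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        train_d = dict(d.get("train", {}))
        aug = AugmentParams(**train_d.pop("augment", {}))
        return cls(
            phantom=PhantomConfig(**_tuplify(d.get("phantom", {}))),
            preprocess=PreprocessSpec(**_tuplify(d.get("preprocess", {}))),
            model=SAFNetConfig(**_tuplify(d.get("model", {}))),
            train=TrainConfig(augment=aug, **train_d),
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
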