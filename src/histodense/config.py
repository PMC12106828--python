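"""Run configuration: one JSON document drives every pipeline stage.

Unknown keys are rejected so typos fail loudly; the canonical-JSON SHA-256
hash of the config is recorded in every run record for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .classify import DCNNConfig, SCNNConfig
from .segmentation import UNetSAMConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


def _strict(cls, data: dict[str, Any]):
    """Build a dataclass from a dict, rejecting unknown keys; lists->tuples."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


@dataclass(frozen=True)
class PathsBlock:
    input_root: str = "data/synthetic"
    output_root: str = "runs/out"


@dataclass(frozen=True)
class CalibrationBlock:
    pps: float = 6.5  # sensor pixel pitch, micrometres


@dataclass(frozen=True)
class PatchingBlock:
    mode: str = "grid6"
    patch: int = 224


@dataclass(frozen=True)
class PreprocessBlock:
    sigma: float = 1.0
    hematoxylin: tuple[float, float, float] = (0.65, 0.70, 0.29)
    eosin: tuple[float, float, float] = (0.07, 0.99, 0.11)
    background_intensity: float = 255.0
    rotation_range: float = 20.0
    zoom_range: float = 0.10
    shear_range: float = 0.10
    rescale: float = 0.00392156862745098  # 1/255
    segmenter_input: str = "rgb"  # or "hematoxylin"


@dataclass(frozen=True)
class StratifyBlock:
    ratio: tuple[float, float, float] = (30.0, 30.0, 40.0)
    basis: str = "fraction_of_max"
    min_area: int = 10
    connectivity: int = 8
    per_magnification: bool = True
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)


@dataclass(frozen=True)
class SynthBlock:
    width: int = 700
    height: int = 460
    magnifications: tuple[str, ...] = ("40X", "400X")
    n_benign: int = 5
    n_malignant: int = 6
    malignant_count_ranges: tuple[tuple[int, int], ...] = ((30, 50), (120, 160), (260, 320))
    noise_sd: float = 2.0


@dataclass(frozen=True)
class ClassifyBlock:
    model: str = "scnn"  # or "dcnn"
    input_size: int = 64  # classifier input resolution (patches are resized)
    scnn: SCNNConfig = field(default_factory=SCNNConfig)
    dcnn: DCNNConfig = field(default_factory=DCNNConfig)


@dataclass(frozen=True)
class SegTrainBlock:
    train_patch: int = 64  # training crop size, divisible by the down factor
    crops_per_image: int = 4
    validation_split: float = 0.2


@dataclass(frozen=True)
class RunConfig:
    paths: PathsBlock = field(default_factory=PathsBlock)
    calibration: CalibrationBlock = field(default_factory=CalibrationBlock)
    patching: PatchingBlock = field(default_factory=PatchingBlock)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    segmentation: UNetSAMConfig = field(default_factory=UNetSAMConfig)
    seg_training: SegTrainBlock = field(default_factory=SegTrainBlock)
    stratify: StratifyBlock = field(default_factory=StratifyBlock)
    classify: ClassifyBlock = field(default_factory=ClassifyBlock)
    synth: SynthBlock = field(default_factory=SynthBlock)
    seed: int = 0
    log_level: str = "INFO"

    _NESTED = {
        "paths": PathsBlock,
        "calibration": CalibrationBlock,
        "patching": PatchingBlock,
        "preprocess": PreprocessBlock,
        "segmentation": UNetSAMConfig,
        "seg_training": SegTrainBlock,
        "stratify": StratifyBlock,
        "classify": ClassifyBlock,
        "synth": SynthBlock,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            sub = cls._NESTED.get(key)
            if sub is not None:
                if key == "classify":
                    value = dict(value)
                    if "scnn" in value:
                        value["scnn"] = _strict(SCNNConfig, value["scnn"])
                    if "dcnn" in value:
                        value["dcnn"] = _strict(DCNNConfig, value["dcnn"])
                    kwargs[key] = _strict(ClassifyBlock, value)
                elif key == "synth":
                    value = dict(value)
                    if "malignant_count_ranges" in value:
                        value["malignant_count_ranges"] = tuple(
                            tuple(r) for r in value["malignant_count_ranges"]
                        )
                    kwargs[key] = _strict(SynthBlock, value)
                else:
                    kwargs[key] = _strict(sub, value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a JSON run config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return RunConfig.from_dict(json.load(fh))


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON form (first 12 hex digits)."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
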