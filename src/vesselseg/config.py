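"""Validated run configuration.

A single human-editable YAML file; unspecified fields take the toolkit
defaults (contrast-CT liver-vessel settings: C=128 token channels, 4x4x4
attention windows, weighted-dice β=6, lr 3e-5 with momentum 0.9 and weight
decay 2e-3 over 750 epochs at batch 2, 128x128x96 inference patches with
24-voxel overlap, 180 mm³ minimum component volume).  Every field is
range-checked before use and unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    base_channels: int = Field(128, ge=2, description="token channels C after embedding")
    window_size: tuple[int, int, int] = (4, 4, 4)
    depths: tuple[int, ...] = (2, 2, 2)          # blocks per stage; each even
    heads_per_stage: tuple[int, ...] | None = None
    position_mode: str = "inductive_bias"        # | relative_only | none
    downsample_mode: str = "conv"                # | patch_merging
    upsample_mode: str = "transposed_conv"       # | trilinear | patch_expanding
    local_path: bool = True
    embed_kernels: tuple[int, int] = (7, 3)
    mlp_ratio: int = Field(4, ge=1)

    @field_validator("window_size")
    @classmethod
    def _positive_window(cls, v):
        if any(m < 1 for m in v):
            raise ValueError("window sides must be >= 1")
        return v

    @field_validator("depths")
    @classmethod
    def _even_depths(cls, v):
        if not v or any(d <= 0 or d % 2 for d in v):
            raise ValueError("each stage depth must be a positive even block count")
        return v

    @field_validator("position_mode")
    @classmethod
    def _pos_mode(cls, v):
        if v not in ("inductive_bias", "relative_only", "none"):
            raise ValueError(f"unknown position_mode {v!r}")
        return v

    @field_validator("downsample_mode")
    @classmethod
    def _down_mode(cls, v):
        if v not in ("conv", "patch_merging"):
            raise ValueError(f"unknown downsample_mode {v!r}")
        return v

    @field_validator("upsample_mode")
    @classmethod
    def _up_mode(cls, v):
        if v not in ("transposed_conv", "trilinear", "patch_expanding"):
            raise ValueError(f"unknown upsample_mode {v!r}")
        return v


class LossConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    beta: float = Field(6.0, gt=0, description="misclassification penalty weight")
    smooth: float = Field(1e-5, ge=0)


class TrainingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    learning_rate: float = Field(3e-5, gt=0)
    momentum: float = Field(0.9, ge=0, lt=1)
    weight_decay: float = Field(2e-3, ge=0)
    epochs: int = Field(750, ge=1)
    batch_size: int = Field(2, ge=1)
    seed: int = 0
    optimizer: str = "sgd"                       # | adam
    foreground_biased_sampling: bool = True
    patch_size: tuple[int, int, int] = (128, 128, 96)

    @field_validator("optimizer")
    @classmethod
    def _opt(cls, v):
        if v not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {v!r}")
        return v


class InferenceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patch_size: tuple[int, int, int] = (128, 128, 96)
    overlap: int = Field(24, ge=0, description="voxels of overlap between patches")
    overlap_is_step: bool = False                # alternative reading: step = 24
    aggregation: str = "mean"                    # | gaussian
    threshold: float = Field(0.5, ge=0, le=1)

    @field_validator("aggregation")
    @classmethod
    def _agg(cls, v):
        if v not in ("mean", "gaussian"):
            raise ValueError(f"unknown aggregation {v!r}")
        return v


class PostprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_component_mm3: float = Field(180.0, ge=0)
    morphological_close: bool = False


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: ModelConfig = ModelConfig()
    loss: LossConfig = LossConfig()
    training: TrainingConfig = TrainingConfig()
    inference: InferenceConfig = InferenceConfig()
    postprocess: PostprocessConfig = PostprocessConfig()

    @model_validator(mode="after")
    def _window_divides_token_grid(self):
        """The window must tile the token grid the inference patch produces."""
        for patch in (self.inference.patch_size, self.training.patch_size):
            for size, m in zip(patch, self.model.window_size):
                if size % 4:
                    raise ValueError(f"patch side {size} not divisible by the "
                                     "embedding stride 4")
                if (size // 4) % m:
                    raise ValueError(
                        f"window side {m} does not divide token-grid side {size // 4} "
                        f"(patch side {size} after stride-4 embedding)")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def tiny_config(seed: int = 0) -> RunConfig:
    """Desk-scale preset: C=16, one stage pair, 32³ patches, lr 0.05.

    Small enough to train on a single CPU core in seconds per step while
    exercising every architectural component; used by the overfit checks.
    """
    return RunConfig.model_validate({
        "model": {"base_channels": 16, "depths": (2,)},
        "training": {"learning_rate": 0.05, "weight_decay": 0.0,
                     "patch_size": (32, 32, 32), "batch_size": 1, "seed": seed},
        "inference": {"patch_size": (32, 32, 32), "overlap": 8},
    })


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing fields take the defaults above; unknown keys or out-of-range
    values raise a validation error listing each offending field.  ``None``
    (or an empty file) yields the full default configuration.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    if overrides:
        for dotted, value in overrides.items():
            parts = dotted.split(".")
            node = raw
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = value
    return RunConfig.model_validate(raw)
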