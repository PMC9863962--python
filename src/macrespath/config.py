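"""Run configuration: YAML loading, schema validation, seed fan-out.

A run config is a nested set of blocks (synthetic, patch, augment, model,
attention, loss, train, distill, infer) over the package's dataclasses.
Unknown keys are rejected by name; value bounds are enforced by each
dataclass's own validation.  One global seed fans out to per-stage seeds by
hashing the stage name (CRC32), so every stage is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .losses import DistillParams, FocalParams
from .models import ModelConfig
from .patches import PatchSpec
from .synthetic import SyntheticConfig
from .training import TrainConfig


@dataclasses.dataclass
class AttentionSettings:
    X: int = 32
    theta_c: float = 0.5
    crop_size: int | None = None

    def __post_init__(self) -> None:
        if self.X < 1:
            raise ValueError("attention.X must be >= 1")
        if not (0.0 <= self.theta_c < 1.0):
            raise ValueError("attention.theta_c must be in [0,1)")


@dataclasses.dataclass
class LossSettings:
    type: str = "focal"  # focal | cross_entropy | label_smoothing
    alpha: float = 0.25
    gamma: float = 2.0
    smoothing: float = 0.1

    def __post_init__(self) -> None:
        if self.type not in ("focal", "cross_entropy", "label_smoothing"):
            raise ValueError(f"unknown loss.type {self.type!r}")


@dataclasses.dataclass
class InferSettings:
    threshold: float = 0.5
    unet_base_width: int = 8
    unet_depth: int = 2


_BLOCKS = {
    "synthetic": SyntheticConfig,
    "patch": PatchSpec,
    "augment": AugmentConfig,
    "model": ModelConfig,
    "attention": AttentionSettings,
    "loss": LossSettings,
    "train": TrainConfig,
    "distill": DistillParams,
    "infer": InferSettings,
}

_TUPLE_FIELDS = {"lesion_fraction_range", "enabled_ops", "dares_layers",
                 "spp_levels", "stage_blocks"}


@dataclasses.dataclass
class RunConfig:
    synthetic: SyntheticConfig
    patch: PatchSpec
    augment: AugmentConfig
    model: ModelConfig
    attention: AttentionSettings
    loss: LossSettings
    train: TrainConfig
    distill: DistillParams
    infer: InferSettings
    seed: int = 0
    output_root: str = "runs"

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the global seed and the stage name."""
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)

    def to_dict(self) -> dict:
        d = {name: dataclasses.asdict(getattr(self, name)) for name in _BLOCKS}
        d["seed"] = self.seed
        d["output_root"] = self.output_root
        # texture_params keys must survive YAML round-trip as ints
        return d

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _build_block(name: str, cls, raw: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in block {name!r}"
                         f" (e.g. {name}.{sorted(unknown)[0]})")
    kwargs = {}
    for key, value in raw.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        if key == "texture_params" and isinstance(value, dict):
            value = {int(k): {kk: tuple(vv) if isinstance(vv, list) else vv
                              for kk, vv in v.items()}
                     for k, v in value.items()}
        if key == "probabilities" and isinstance(value, dict):
            value = {str(k): float(v) for k, v in value.items()}
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid block {name!r}: {exc}") from exc


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; ``None``/empty file -> defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    if overrides:
        for dotted, value in overrides.items():
            block, _, key = dotted.partition(".")
            raw.setdefault(block, {})[key] = value
    top_unknown = set(raw) - set(_BLOCKS) - {"seed", "output_root"}
    if top_unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(top_unknown)}")
    blocks = {name: _build_block(name, cls, raw.get(name) or {})
              for name, cls in _BLOCKS.items()}
    return RunConfig(seed=int(raw.get("seed", 0)),
                     output_root=str(raw.get("output_root", "runs")),
                     **blocks)
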