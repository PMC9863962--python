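"""Random-combination, on-the-fly image augmentation.

Each tile in a batch independently receives a random subset of the enabled
operations (each included with its own probability), applied in a fixed
listing order: flips, rotation, saturation jitter, additive Gaussian noise,
outline extraction, smoothing.  Augmentation happens in memory per batch —
nothing is persisted — and never touches labels or masks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

#: canonical application order
ALL_OPS = (
    "random_flip", "random_rotation", "horizontal_flip", "vertical_flip",
    "saturation_jitter", "gaussian_noise", "contour_extract", "smoothing",
)


@dataclasses.dataclass
class AugmentConfig:
    enabled_ops: tuple[str, ...] = ALL_OPS
    probabilities: dict[str, float] = dataclasses.field(default_factory=dict)
    rotation_degrees: float = 30.0
    rotation_right_angles: bool = False  # rotate by multiples of 90 deg only
    saturation_range: float = 0.3        # factor drawn from 1 +/- range
    noise_sigma: float = 8.0             # pixel units on [0,255]
    contour_weight: float = 0.5
    smoothing_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.enabled_ops) - set(ALL_OPS)
        if unknown:
            raise ValueError(f"unknown augmentation op(s): {sorted(unknown)}")
        for op, p in self.probabilities.items():
            if op not in ALL_OPS:
                raise ValueError(f"probability given for unknown op {op!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {op!r} must be in [0,1]")
        if not (0.0 < self.rotation_degrees <= 180.0):
            raise ValueError("rotation_degrees must be in (0,180]")

    def prob(self, op: str) -> float:
        return self.probabilities.get(op, 0.5)


def gaussian_noise(tile: np.ndarray, sigma: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Additive zero-mean Gaussian noise, clipped to [0,255]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return tile.copy()
    noisy = tile.astype(np.float32) + rng.normal(0.0, sigma, tile.shape)
    return np.clip(np.round(noisy), 0, 255).astype(np.uint8)


def _saturation(tile: np.ndarray, factor: float) -> np.ndarray:
    gray = tile.astype(np.float32).mean(axis=2, keepdims=True)
    out = gray + factor * (tile.astype(np.float32) - gray)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _rotate(tile: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.rotation_right_angles:
        k = int(rng.integers(1, 4))
        return np.rot90(tile, k).copy()
    angle = float(rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees))
    out = ndimage.rotate(tile.astype(np.float32), angle, axes=(0, 1),
                         reshape=False, mode="reflect", order=1)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _contour(tile: np.ndarray, weight: float) -> np.ndarray:
    gray = tile.astype(np.float32).mean(axis=2)
    mag = np.hypot(ndimage.sobel(gray, axis=0), ndimage.sobel(gray, axis=1))
    if mag.max() > 0:
        mag = mag / mag.max() * 255.0
    blended = (1.0 - weight) * tile.astype(np.float32) + weight * mag[..., None]
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def _smooth(tile: np.ndarray, sigma: float) -> np.ndarray:
    out = ndimage.gaussian_filter(tile.astype(np.float32), (sigma, sigma, 0))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def augment_tile(tile: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Apply a randomly sampled composition of enabled ops to one tile."""
    out = tile
    for op in ALL_OPS:
        if op not in cfg.enabled_ops:
            continue
        if rng.random() >= cfg.prob(op):
            continue
        if op == "random_flip":
            out = np.flip(out, axis=int(rng.integers(0, 2))).copy()
        elif op == "horizontal_flip":
            out = np.flip(out, axis=1).copy()
        elif op == "vertical_flip":
            out = np.flip(out, axis=0).copy()
        elif op == "random_rotation":
            out = _rotate(out, cfg, rng)
        elif op == "saturation_jitter":
            factor = float(rng.uniform(1.0 - cfg.saturation_range,
                                       1.0 + cfg.saturation_range))
            out = _saturation(out, factor)
        elif op == "gaussian_noise":
            out = gaussian_noise(out, cfg.noise_sigma, rng)
        elif op == "contour_extract":
            out = _contour(out, cfg.contour_weight)
        elif op == "smoothing":
            out = _smooth(out, cfg.smoothing_sigma)
    return out


def augment_batch(batch: np.ndarray | list[np.ndarray], cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Augment every tile of a batch independently; deterministic given rng
    state; output shape equals input shape."""
    tiles = np.asarray(batch)
    if tiles.ndim != 4 or tiles.shape[-1] != 3:
        raise ValueError("batch must be N x H x W x 3")
    return np.stack([augment_tile(t, cfg, rng) for t in tiles])
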