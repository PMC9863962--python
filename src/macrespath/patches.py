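"""Patch extraction and cleaning for whole-slide images.

Slides are tiled with a sliding window (default 512 px window, 256 px
stride, so adjacent windows overlap by half).  A window is kept only when
the annotated lesion covers strictly more than the coverage threshold
(default 3/4) of its area, which keeps patches dominated by tumor tissue.
Kept patches are then cleaned by encoded size: tiles whose lossless encoding
falls below a byte threshold (default 330 KiB) contain mostly empty or
scattered tissue and are dropped.  Finally per-channel normalisation
statistics are fitted on training patches only.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import WSIRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PatchSpec:
    patch_size: int = 512
    stride: int = 256
    coverage_threshold: float = 0.75
    min_encoded_bytes: int = 330 * 1024
    codec: str = "png"  # "png" | "jpeg-q95"

    def __post_init__(self) -> None:
        if not (0 < self.stride <= self.patch_size):
            raise ValueError("require 0 < stride <= patch_size")
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("require 0 < coverage_threshold <= 1")
        if self.min_encoded_bytes < 0:
            raise ValueError("min_encoded_bytes must be >= 0")
        if self.codec not in ("png", "jpeg-q95"):
            raise ValueError(f"unknown codec {self.codec!r}")

    def scaled_min_bytes(self) -> int:
        """Byte threshold scaled by (patch_size/512)^2 for non-default sizes."""
        return int(round(self.min_encoded_bytes * (self.patch_size / 512) ** 2))


@dataclasses.dataclass
class PatchRecord:
    pixels: np.ndarray          # patch_size x patch_size x 3 uint8
    origin: tuple[int, int]     # (row, col), 0-based, top-left in source
    coverage: float
    label: int
    slide_id: str


@dataclasses.dataclass
class NormalizationStats:
    mean: np.ndarray  # per-channel, pixel scale [0,255]
    std: np.ndarray
    computed_over: list[str]

    def __post_init__(self) -> None:
        if not (np.asarray(self.std) > 0).all():
            raise ValueError("std components must be strictly positive")

    def apply(self, pixels: np.ndarray) -> np.ndarray:
        """(x - mean) / std per channel; accepts uint8 or float input."""
        return (pixels.astype(np.float32) - self.mean.astype(np.float32)) / self.std.astype(np.float32)


def enumerate_windows(height: int, width: int, spec: PatchSpec) -> list[tuple[int, int]]:
    """All fully-contained window origins on the stride grid, row-major.

    Windows are half-open ``[r, r+patch) x [c, c+patch)``; incomplete edge
    windows are dropped, never padded.
    """
    p, s = spec.patch_size, spec.stride
    if height < p or width < p:
        warnings.warn(
            f"image {height}x{width} smaller than patch size {p}; no windows",
            stacklevel=2,
        )
        return []
    rows = range(0, height - p + 1, s)
    cols = range(0, width - p + 1, s)
    return [(r, c) for r in rows for c in cols]


def extract_patches(slide: WSIRecord, spec: PatchSpec,
                    region_mask: np.ndarray | None = None) -> list[PatchRecord]:
    """Tile a slide and keep windows with annotated-region coverage strictly
    above the threshold.  Patch label = slide label (masks delineate one
    tumor type per slide).  ``region_mask`` overrides the slide's own mask
    (used for normal slides, where the annotated region is all tissue)."""
    mask = slide.mask if region_mask is None else np.asarray(region_mask)
    if slide.image.shape[:2] != mask.shape:
        raise ValueError("image/mask shape mismatch")
    h, w = mask.shape
    p = spec.patch_size
    # summed-area table makes per-window coverage O(1)
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = mask.astype(np.int64).cumsum(0).cumsum(1)
    kept: list[PatchRecord] = []
    area = p * p
    for r, c in enumerate_windows(h, w, spec):
        ones = int(integral[r + p, c + p] - integral[r, c + p]
                   - integral[r + p, c] + integral[r, c])
        coverage = ones / area
        if coverage > spec.coverage_threshold:
            kept.append(PatchRecord(
                pixels=slide.image[r:r + p, c:c + p].copy(),
                origin=(r, c),
                coverage=coverage,
                label=slide.label,
                slide_id=slide.slide_id,
            ))
    return kept


def encoded_size(pixels: np.ndarray, codec: str = "png") -> int:
    """Byte length of the tile under the given codec."""
    buf = io.BytesIO()
    img = Image.fromarray(pixels)
    if codec == "png":
        img.save(buf, format="PNG")
    elif codec == "jpeg-q95":
        img.save(buf, format="JPEG", quality=95)
    else:
        raise ValueError(f"unknown codec {codec!r}")
    return buf.getbuffer().nbytes


def size_filter(patch: PatchRecord, spec: PatchSpec) -> tuple[bool, int]:
    """Encoded-size cleaning rule: returns (keep, encoded_bytes).

    The byte threshold scales with patch area when patch_size differs from
    the 512-px reference.
    """
    try:
        nbytes = encoded_size(patch.pixels, spec.codec)
    except Exception as exc:  # codec failure -> discard, keep pipeline alive
        logger.error("codec failure on %s@%s: %s", patch.slide_id, patch.origin, exc)
        return False, 0
    keep = nbytes >= spec.scaled_min_bytes()
    logger.debug("size_filter %s@%s: %d bytes -> %s",
                 patch.slide_id, patch.origin, nbytes, "keep" if keep else "drop")
    return keep, nbytes


def tissue_fraction_filter(patch: PatchRecord, min_fraction: float = 0.5,
                           brightness_cutoff: int = 240) -> bool:
    """Alternative cleaning rule: keep patches whose non-background (dark
    enough) pixel fraction reaches ``min_fraction``."""
    gray = patch.pixels.mean(axis=2)
    return float((gray < brightness_cutoff).mean()) >= min_fraction


def clean_patches(patches: list[PatchRecord], spec: PatchSpec,
                  use_tissue_filter: bool = False) -> tuple[list[PatchRecord], list[int]]:
    """Apply the size filter; returns (kept patches, encoded byte lengths)."""
    kept, sizes = [], []
    for patch in patches:
        if use_tissue_filter:
            ok, nbytes = tissue_fraction_filter(patch), -1
        else:
            ok, nbytes = size_filter(patch, spec)
        if ok:
            kept.append(patch)
            sizes.append(nbytes)
    return kept, sizes


def fit_normalization(train_patches: list[PatchRecord]) -> NormalizationStats:
    """Per-channel mean/std over the training patches only (no leakage)."""
    if not train_patches:
        raise ValueError("cannot fit normalization on an empty collection")
    stack = np.stack([p.pixels for p in train_patches]).astype(np.float64)
    mean = stack.mean(axis=(0, 1, 2))
    std = stack.std(axis=(0, 1, 2))
    if (std <= 0).any():
        raise ValueError(f"zero-variance channel(s) in training patches: std={std}")
    return NormalizationStats(mean=mean, std=std,
                              computed_over=sorted({p.slide_id for p in train_patches}))


def extract_dataset_patches(splits: dict[str, list[WSIRecord]], spec: PatchSpec,
                            apply_size_filter: bool = True,
                            ) -> dict[str, list[PatchRecord]]:
    """Run tiling + cleaning over every split of a slide dataset."""
    out: dict[str, list[PatchRecord]] = {}
    for split, slides in splits.items():
        patches: list[PatchRecord] = []
        for slide in slides:
            region = np.ones_like(slide.mask) if slide.label == 0 else None
            patches.extend(extract_patches(slide, spec, region_mask=region))
        if apply_size_filter:
            patches, _ = clean_patches(patches, spec)
        out[split] = patches
    return out


def write_patches(patches: list[PatchRecord], out_dir: str | Path,
                  spec: PatchSpec) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for patch in patches:
        r, c = patch.origin
        name = f"{patch.slide_id}_r{r}_c{c}.png"
        Image.fromarray(patch.pixels).save(out / name)
        rows.append({
            "slide_id": patch.slide_id, "path": name,
            "origin_row": r, "origin_col": c,
            "coverage": patch.coverage, "label": patch.label,
            "bytes": encoded_size(patch.pixels, spec.codec),
        })
    manifest = out / "patches.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
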