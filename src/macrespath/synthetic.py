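"""Synthetic whole-slide-image generator.

Real eyelid-tumor slides are gigapixel H&E rasters in which a pathologist
delineates a single tumor type per slide.  This module emulates that setting
at desk scale: each synthetic slide is a class-0 (normal-tissue) textured
background, and slides of a tumor class additionally carry one lesion region
filled with a class-conditioned texture, with the binary mask set to 1
exactly there.  Textures are filtered Gaussian noise fields with a per-class
RGB tint, dominant spatial scale, and contrast amplitude, which makes the
four classes separable by small convolutional networks while remaining fully
seed-reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

N_CLASSES = 4
CLASS_NAMES = {0: "normal", 1: "BCC", 2: "MGC", 3: "CM"}

#: per-class texture parameters: RGB tint (base colour), smoothing scale in
#: pixels (dominant texture wavelength), and contrast amplitude.
DEFAULT_TEXTURE_PARAMS: dict[int, dict] = {
    0: {"tint": (232, 196, 212), "sigma": 6.0, "amplitude": 18.0},
    1: {"tint": (120, 80, 160), "sigma": 2.0, "amplitude": 30.0},
    2: {"tint": (90, 140, 110), "sigma": 4.0, "amplitude": 30.0},
    3: {"tint": (150, 90, 70), "sigma": 1.0, "amplitude": 35.0},
}


@dataclasses.dataclass
class SyntheticConfig:
    image_size: int = 1024
    n_slides_per_class: int = 4
    lesion_shape: str = "blob"  # "rectangle" | "blob"
    lesion_fraction_range: tuple[float, float] = (0.2, 0.5)
    texture_params: dict[int, dict] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TEXTURE_PARAMS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(
                f"lesion_fraction_range must satisfy 0 < min <= max <= 1, got {self.lesion_fraction_range}"
            )
        if self.lesion_shape not in ("rectangle", "blob"):
            raise ValueError(f"unknown lesion_shape {self.lesion_shape!r}")
        if set(self.texture_params) != set(range(N_CLASSES)):
            raise ValueError(
                f"texture_params must have exactly {N_CLASSES} entries keyed 0..{N_CLASSES - 1}"
            )


@dataclasses.dataclass
class WSIRecord:
    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray   # H x W uint8 in {0,1}
    label: int
    slide_id: str

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("mask shape must equal image spatial shape")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be in {0,1}")
        if self.label == 0 and self.mask.any():
            raise ValueError("normal slides must have an all-zero mask")


def _texture(shape: tuple[int, int], params: dict, rng: np.random.Generator) -> np.ndarray:
    """Filtered-noise RGB texture field, float in [0,255]."""
    h, w = shape
    tint = np.asarray(params["tint"], dtype=np.float64)
    sigma = float(params["sigma"])
    amp = float(params["amplitude"])
    out = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        field = rng.normal(size=(h, w))
        field = ndimage.gaussian_filter(field, sigma)
        sd = field.std()
        if sd > 0:
            field /= sd
        out[..., c] = tint[c] + amp * field
    return np.clip(out, 0, 255)


def _lesion_mask(size: int, fraction: float, shape: str,
                 rng: np.random.Generator) -> np.ndarray:
    if shape == "rectangle":
        side = int(round(np.sqrt(fraction) * size))
        side = max(1, min(side, size))
        r0 = int(rng.integers(0, size - side + 1))
        c0 = int(rng.integers(0, size - side + 1))
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[r0:r0 + side, c0:c0 + side] = 1
        return mask
    # blob: threshold a smoothed noise field at the (1 - fraction) quantile
    field = ndimage.gaussian_filter(rng.normal(size=(size, size)), size / 8.0)
    thr = np.quantile(field, 1.0 - fraction)
    return (field > thr).astype(np.uint8)


def generate_slide(cfg: SyntheticConfig, class_id: int, rng_seed: int) -> WSIRecord:
    """Render one synthetic slide of the given class, deterministically.

    Class 0 yields pure background with an all-zero mask; tumor classes get a
    lesion whose area fraction is drawn uniformly from
    ``cfg.lesion_fraction_range`` and whose pixels come from that class's
    texture distribution.
    """
    if class_id not in range(N_CLASSES):
        raise ValueError(f"class_id must be in 0..{N_CLASSES - 1}, got {class_id}")
    rng = np.random.default_rng(rng_seed)
    size = cfg.image_size
    img = _texture((size, size), cfg.texture_params[0], rng)
    mask = np.zeros((size, size), dtype=np.uint8)
    if class_id != 0:
        frac = float(rng.uniform(*cfg.lesion_fraction_range))
        mask = _lesion_mask(size, frac, cfg.lesion_shape, rng)
        lesion = _texture((size, size), cfg.texture_params[class_id], rng)
        img = np.where(mask[..., None].astype(bool), lesion, img)
    return WSIRecord(
        image=np.round(img).astype(np.uint8),
        mask=mask,
        label=class_id,
        slide_id=f"s{class_id}_{rng_seed}",
    )


def _split_counts(n: int) -> tuple[int, int, int]:
    """Stratified ~60/20/20 split with at least one slide per partition."""
    if n < 3:
        raise ValueError("need n_slides_per_class >= 3 to stratify")
    n_val = max(1, round(0.2 * n))
    n_test = max(1, round(0.2 * n))
    n_train = n - n_val - n_test
    if n_train < 1:
        n_train, n_val, n_test = n - 2, 1, 1
    return n_train, n_val, n_test


def generate_dataset(cfg: SyntheticConfig) -> dict[str, list[WSIRecord]]:
    """Generate ``4 * n_slides_per_class`` slides, stratified into splits."""
    rng = np.random.default_rng(cfg.seed)
    splits: dict[str, list[WSIRecord]] = {"train": [], "val": [], "test": []}
    n = cfg.n_slides_per_class
    n_train, n_val, n_test = _split_counts(n)
    for class_id in range(N_CLASSES):
        seeds = rng.integers(0, 2**31 - 1, size=n)
        order = rng.permutation(n)
        assignment = (["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
        for idx, split in zip(order, assignment):
            splits[split].append(generate_slide(cfg, class_id, int(seeds[idx])))
    return splits


def write_dataset(splits: dict[str, list[WSIRecord]], out_dir: str | Path) -> Path:
    """Write images/masks as PNG plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, records in splits.items():
        for rec in records:
            img_path = out / f"{rec.slide_id}_image.png"
            mask_path = out / f"{rec.slide_id}_mask.png"
            Image.fromarray(rec.image).save(img_path)
            Image.fromarray(rec.mask * 255).save(mask_path)
            rows.append({
                "slide_id": rec.slide_id,
                "image_path": img_path.name,
                "mask_path": mask_path.name,
                "label": rec.label,
                "split": split,
            })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_slide(image_path: str | Path, mask_path: str | Path | None,
               label: int, slide_id: str | None = None) -> WSIRecord:
    image = np.asarray(Image.open(image_path).convert("RGB"))
    if mask_path is None:
        mask = np.zeros(image.shape[:2], dtype=np.uint8)
    else:
        mask = (np.asarray(Image.open(mask_path).convert("L")) > 127).astype(np.uint8)
    return WSIRecord(image=image, mask=mask, label=label,
                     slide_id=slide_id or Path(image_path).stem)
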