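"""Desk-scale experiment recipes.

These are the study conditions the package's integration benchmarks run
under: 64-px patches from 256-px synthetic slides (the same tiling
arithmetic as gigapixel slides with 512-px windows, scaled by 8), a
miniature classifier at 1/8 width with one bottleneck per stage, five
teacher epochs, and Adam at 1e-3.  The encoded-size cleaning rule is
disabled here because it is calibrated for 512-px tiles of real stained
tissue, not 64-px noise-texture tiles.  Every recipe is deterministic in
its seed.
"""

from __future__ import annotations

import numpy as np

from . import models, patches, synthetic, training
from .losses import DistillParams
from .metrics import segmentation_metrics
from .inference import predict_slide

#: patch grid used by all miniature runs
MINIATURE_SPEC = patches.PatchSpec(patch_size=64, stride=32, min_encoded_bytes=0)


def miniature_dataset(seed: int, n_slides_per_class: int = 15,
                      lesion_shape: str = "blob"):
    """Synthetic slides -> cleaned patch arrays per split.

    Returns (data, splits, spec) where ``data`` maps split -> (X, y).
    Lesion fractions 0.35-0.6 keep enough fully-covered windows per tumor
    slide under the strict >3/4 coverage rule.
    """
    cfg = synthetic.SyntheticConfig(
        image_size=256, n_slides_per_class=n_slides_per_class,
        lesion_shape=lesion_shape, lesion_fraction_range=(0.35, 0.6),
        seed=seed)
    splits = synthetic.generate_dataset(cfg)
    patch_splits = patches.extract_dataset_patches(splits, MINIATURE_SPEC)
    data = {s: training.patches_to_arrays(p) for s, p in patch_splits.items()}
    return data, splits, MINIATURE_SPEC


def train_miniature_teacher(data: dict, seed: int, epochs: int = 5):
    """Attention-crop teacher at miniature scale (width 1/8, 64-px input)."""
    mcfg = models.miniature_config()
    tcfg = training.TrainConfig(epochs=epochs, batch_size=32, base_lr=1e-3,
                                seed=seed)
    return training.train_teacher(mcfg, data, tcfg)


def distillation_benchmark(teacher, data: dict, seeds=(1, 2, 3),
                           epochs: int = 2) -> dict:
    """Identically-budgeted KD-student vs plain-student arms per seed."""
    scfg = models.plain_student_config(models.miniature_config())
    dp = DistillParams(temperature=4.0, mix=0.7)
    out = {"kd": [], "plain": []}
    for seed in seeds:
        tcfg = training.TrainConfig(epochs=epochs, batch_size=32,
                                    base_lr=1e-3, seed=seed)
        _, r_kd = training.train_student(scfg, data, tcfg, teacher=teacher,
                                         distill=dp)
        _, r_pl = training.train_student(scfg, data, tcfg, teacher=None)
        out["kd"].append(r_kd["best_val_accuracy"])
        out["plain"].append(r_pl["best_val_accuracy"])
    out["kd_mean"] = float(np.mean(out["kd"]))
    out["plain_mean"] = float(np.mean(out["plain"]))
    return out


def segmentation_tiles(slides, n_tiles: int, tile: int,
                       rng: np.random.Generator):
    """Random windows with their mask crops (mixed coverage, for U-Nets)."""
    X, Y = [], []
    for _ in range(n_tiles):
        s = slides[rng.integers(len(slides))]
        r = int(rng.integers(0, s.image.shape[0] - tile + 1))
        c = int(rng.integers(0, s.image.shape[1] - tile + 1))
        X.append(s.image[r:r + tile, c:c + tile])
        Y.append(s.mask[r:r + tile, c:c + tile])
    return np.stack(X), np.stack(Y)


def train_lesion_unets(splits: dict, stats, seed: int, n_tiles: int = 160,
                       epochs: int = 3) -> dict:
    """One binary-lesion U-Net per tumor class, trained on that class's
    training slides."""
    rng = np.random.default_rng(seed)
    unets = {}
    for class_id in (1, 2, 3):
        class_slides = [s for s in splits["train"] if s.label == class_id]
        X, Y = segmentation_tiles(class_slides, n_tiles, MINIATURE_SPEC.patch_size, rng)
        tcfg = training.TrainConfig(epochs=epochs, batch_size=16,
                                    base_lr=3e-3, seed=seed + class_id)
        model, _ = training.train_unet(X, Y, tcfg, base_width=8, depth=2,
                                       stats=stats)
        unets[class_id] = (model, stats)
    return unets


def wsi_benchmark(classifier, stats, unets: dict, slides, spec) -> dict:
    """Slide-level accuracy and lesion IoU of the full pipeline."""
    correct, ious = 0, []
    for slide in slides:
        pred = predict_slide(slide, classifier, stats, unets, spec)
        correct += int(pred.slide_class == slide.label)
        ious.append(segmentation_metrics(pred.lesion_mask, slide.mask)["iou"])
    return {
        "slide_accuracy": correct / len(slides),
        "mean_iou": float(np.mean(ious)),
        "ious": ious,
    }
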