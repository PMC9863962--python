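"""Backbone-Attention-Crop head (BACM).

From the backbone's last feature map, a 1x1 convolution produces X spatial
attention maps.  One map per image is selected uniformly at random (seeded),
min-max normalised to [0,1], thresholded strictly at ``theta_c``, and
upsampled to image resolution; the tight bounding box over the positive
pixels defines a crop of the original image, which is resized bilinearly and
fed through the network a second time.  The training loss is the mean of the
original-pass and crop-pass losses.

Degenerate (constant) attention maps fall back to a full-image crop so
training never halts on a flat map.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AttentionStack:
    maps: np.ndarray      # X x h x w, real-valued, one image
    selected_index: int

    def __post_init__(self) -> None:
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise ValueError("maps must be X x h x w with X >= 1")
        if not (0 <= self.selected_index < self.maps.shape[0]):
            raise ValueError("selected_index out of range")


@dataclasses.dataclass
class CropRegion:
    box: tuple[int, int, int, int]  # (row_min, row_max, col_min, col_max), half-open
    mask: np.ndarray                # binary, image resolution

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.box
        h, w = self.mask.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"empty or out-of-bounds box {self.box}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


class AttentionHead(nn.Module):
    """1x1 convolution producing X attention maps from the feature map."""

    def __init__(self, in_channels: int, n_maps: int, seed: int = 0):
        if n_maps < 1:
            raise ValueError("need at least one attention map")
        self.conv = nn.Conv2d(in_channels, n_maps, 1,
                              rng=np.random.default_rng(seed))
        self.n_maps = n_maps

    def forward(self, fmap: Tensor) -> Tensor:
        return self.conv(fmap)


def attention_maps(feature_map: np.ndarray | Tensor, head: AttentionHead,
                   rng: np.random.Generator) -> list[AttentionStack]:
    """Per-image attention stacks with a seeded random map selection."""
    fmap = feature_map if isinstance(feature_map, Tensor) else Tensor(feature_map)
    maps = head(Tensor(fmap.data)).data  # head needs no gradient: crop is discrete
    return [AttentionStack(maps=np.ascontiguousarray(m.transpose(2, 0, 1)),
                           selected_index=int(rng.integers(head.n_maps)))
            for m in maps]


def normalize_attention(amap: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max rescale to [0,1]: ``(A - min A) / (max A - min A)``.

    Returns (normalized map, degenerate flag); a constant map yields all
    zeros with the flag set.
    """
    amap = np.asarray(amap, dtype=np.float64)
    if amap.size == 0:
        raise ValueError("attention map is empty")
    lo, hi = amap.min(), amap.max()
    if hi == lo:
        return np.zeros_like(amap), True
    return (amap - lo) / (hi - lo), False


def binarize(normalized: np.ndarray, theta_c: float,
             image_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Strict threshold: mask = 1 where value > theta_c.

    An all-zero result (degenerate map, or theta_c above every value) falls
    back to an all-ones mask — the crop is then the whole image.  If
    ``image_shape`` is given the mask is upsampled to it by nearest
    neighbour.
    """
    if not (0.0 <= theta_c < 1.0):
        raise ValueError("theta_c must be in [0,1)")
    mask = (np.asarray(normalized) > theta_c).astype(np.uint8)
    if not mask.any():
        logger.debug("degenerate attention mask: falling back to full image")
        mask = np.ones_like(mask)
    if image_shape is not None and mask.shape != tuple(image_shape):
        h, w = image_shape
        rows = (np.arange(h) * mask.shape[0] // h).clip(max=mask.shape[0] - 1)
        cols = (np.arange(w) * mask.shape[1] // w).clip(max=mask.shape[1] - 1)
        mask = mask[np.ix_(rows, cols)]
    return mask


def crop_region_from_mask(mask: np.ndarray) -> CropRegion:
    """Tight bounding box over all positive pixels (fallback: whole image)."""
    mask = np.asarray(mask).astype(np.uint8)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        logger.debug("empty crop mask: falling back to full image")
        h, w = mask.shape
        return CropRegion(box=(0, h, 0, w), mask=np.ones_like(mask))
    return CropRegion(box=(int(rows[0]), int(rows[-1]) + 1,
                           int(cols[0]), int(cols[-1]) + 1), mask=mask)


def crop_and_resize(image: np.ndarray, region: CropRegion,
                    out_size: int) -> np.ndarray:
    """Crop the region's bounding box and resize bilinearly to
    ``out_size x out_size``; channels (trailing axis) are preserved."""
    r0, r1, c0, c1 = region.box
    crop = image[r0:r1, c0:c1]
    zoom = (out_size / crop.shape[0], out_size / crop.shape[1])
    if crop.ndim == 3:
        zoom = zoom + (1.0,)
    out = ndimage.zoom(crop.astype(np.float32), zoom, order=1,
                       mode="nearest", grid_mode=True)
    if image.dtype == np.uint8:
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out


class BACM(nn.Module):
    """Backbone + attention head + crop-and-reforward training wrapper."""

    def __init__(self, backbone, n_maps: int = 32, theta_c: float = 0.5,
                 crop_size: int | None = None, seed: int = 0):
        if not (0.0 <= theta_c < 1.0):
            raise ValueError("theta_c must be in [0,1)")
        self.backbone = backbone
        self.head = AttentionHead(backbone.feature_channels, n_maps, seed=seed)
        self.theta_c = theta_c
        self.crop_size = crop_size or backbone.cfg.input_size

    def forward(self, x: Tensor) -> Tensor:
        return self.backbone(x)

    def crop_batch(self, raw_batch: np.ndarray, fmap: Tensor,
                   rng: np.random.Generator) -> np.ndarray:
        """Attention-guided crops of a raw NHWC uint8 batch."""
        stacks = attention_maps(fmap, self.head, rng)
        crops = []
        for img, stack in zip(raw_batch, stacks):
            norm, _ = normalize_attention(stack.maps[stack.selected_index])
            mask = binarize(norm, self.theta_c, image_shape=img.shape[:2])
            region = crop_region_from_mask(mask)
            crops.append(crop_and_resize(img, region, self.crop_size))
        return np.stack(crops)


def bacm_forward_loss(model: BACM, raw_batch: np.ndarray, labels: np.ndarray,
                      loss_fn, preprocess, rng: np.random.Generator,
                      ) -> tuple[Tensor, Tensor, Tensor]:
    """Two-pass BACM loss: mean of the original-pass and crop-pass losses.

    ``raw_batch`` is NHWC uint8; ``preprocess`` maps it to the normalized
    NCHW float input (the crop pass goes through the same contract).
    Returns (loss, original logits, crop logits); gradients flow through
    both forward passes.
    """
    fmap, logits_orig = model.backbone.forward_features(Tensor(preprocess(raw_batch)))
    crops = model.crop_batch(raw_batch, fmap, rng)
    logits_crop = model.backbone(Tensor(preprocess(crops)))
    loss = 0.5 * loss_fn(logits_orig, labels) + 0.5 * loss_fn(logits_crop, labels)
    return loss, logits_orig, logits_crop
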