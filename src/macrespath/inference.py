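"""Slide-level inference: tile, classify, route to per-class segmentation,
reassemble, and render attention heatmaps.

At inference no lesion mask exists, so every enumerated window is
classified (the training-time coverage rule does not apply).  The
slide-level class is a majority vote over windows called as tumor; a slide
with only normal calls is normal; ties break by the higher mean class
probability.  Tumor-called windows are segmented by the network trained for
the called class and the per-pixel probabilities of overlapping windows are
averaged before thresholding, so seams between overlapping tiles are
smoothed out.  Edge pixels not covered by any full window stay zero and are
reported as uncovered.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .attention import BACM, attention_maps, normalize_attention
from .nn import Tensor
from .patches import NormalizationStats, PatchSpec, enumerate_windows
from .synthetic import WSIRecord
from .training import make_preprocess


@dataclasses.dataclass
class SlidePrediction:
    slide_id: str
    origins: list[tuple[int, int]]
    probabilities: np.ndarray        # n_patches x n_classes, rows sum to 1
    slide_class: int
    lesion_mask: np.ndarray          # slide resolution, binary
    heatmap: np.ndarray              # slide resolution, [0,1]
    covered: np.ndarray              # slide resolution, bool


def classify_patches(slide: WSIRecord, classifier, stats: NormalizationStats,
                     spec: PatchSpec, batch_size: int = 16,
                     ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Class probabilities for every enumerated window of the slide."""
    preprocess = make_preprocess(stats)
    origins = enumerate_windows(*slide.image.shape[:2], spec)
    p = spec.patch_size
    classifier.eval()
    probs = []
    for i in range(0, len(origins), batch_size):
        tiles = np.stack([slide.image[r:r + p, c:c + p]
                          for r, c in origins[i:i + batch_size]])
        logits = classifier(Tensor(preprocess(tiles))).data
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs.append(e / e.sum(axis=1, keepdims=True))
    return origins, np.concatenate(probs) if probs else np.empty((0, 0))


def call_slide_class(probabilities: np.ndarray) -> int:
    """Majority vote over non-normal patch calls; all-normal -> normal;
    ties -> the class with the higher mean probability."""
    if len(probabilities) == 0:
        raise ValueError("need at least one patch")
    calls = probabilities.argmax(axis=1)
    tumor_calls = calls[calls != 0]
    if tumor_calls.size == 0:
        return 0
    counts = np.bincount(tumor_calls, minlength=probabilities.shape[1])
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) == 1:
        return int(tied[0])
    means = probabilities[:, tied].mean(axis=0)
    return int(tied[np.argmax(means)])


def reassemble_average(tile_values: list[np.ndarray],
                       origins: list[tuple[int, int]],
                       slide_shape: tuple[int, int],
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Average per-pixel tile values at slide coordinates.

    Returns (averaged map, coverage counts); pixels covered by no tile get
    value 0 and count 0.
    """
    acc = np.zeros(slide_shape, dtype=np.float64)
    cnt = np.zeros(slide_shape, dtype=np.int64)
    for vals, (r, c) in zip(tile_values, origins):
        h, w = vals.shape
        acc[r:r + h, c:c + w] += vals
        cnt[r:r + h, c:c + w] += 1
    out = np.zeros(slide_shape, dtype=np.float64)
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return out, cnt


def segment_and_reassemble(slide: WSIRecord, slide_class: int,
                           unets: dict[int, tuple], spec: PatchSpec,
                           origins: list[tuple[int, int]],
                           calls: np.ndarray, threshold: float = 0.5,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Slide-level lesion mask from the class-specific segmentation net.

    ``unets`` maps class id -> (model, NormalizationStats).  Tumor-called
    windows are segmented; normal-called windows contribute zeros.
    Overlapping probabilities are averaged, then thresholded.
    """
    if slide_class == 0:
        zeros = np.zeros(slide.image.shape[:2], dtype=np.uint8)
        return zeros, np.zeros_like(zeros, dtype=np.int64)
    if slide_class not in unets:
        raise ValueError(f"no segmentation network for class {slide_class}")
    model, stats = unets[slide_class]
    preprocess = make_preprocess(stats)
    model.eval()
    p = spec.patch_size
    tile_probs, used_origins = [], []
    for (r, c), call in zip(origins, calls):
        if call == 0:
            tile_probs.append(np.zeros((p, p)))
        else:
            tile = slide.image[r:r + p, c:c + p][None]
            logits = model(Tensor(preprocess(tile))).data[0, :, :, 0]
            tile_probs.append(1.0 / (1.0 + np.exp(-logits)))
        used_origins.append((r, c))
    avg, cnt = reassemble_average(tile_probs, used_origins, slide.image.shape[:2])
    return (avg > threshold).astype(np.uint8), cnt


def attention_heatmap(slide: WSIRecord, model: BACM, stats: NormalizationStats,
                      spec: PatchSpec, rng: np.random.Generator | None = None,
                      ) -> np.ndarray:
    """Slide-resolution attention heatmap in [0,1].

    Each window's selected attention map is min-max normalised, upsampled to
    window size by nearest neighbour, placed at the window origin; overlaps
    are averaged.
    """
    rng = rng or np.random.default_rng(0)
    preprocess = make_preprocess(stats)
    origins = enumerate_windows(*slide.image.shape[:2], spec)
    p = spec.patch_size
    model.eval()
    tiles_att = []
    for r, c in origins:
        tile = slide.image[r:r + p, c:c + p][None]
        fmap = model.backbone.features(Tensor(preprocess(tile)))
        stack = attention_maps(fmap, model.head, rng)[0]
        norm, _ = normalize_attention(stack.maps[stack.selected_index])
        rows = (np.arange(p) * norm.shape[0] // p).clip(max=norm.shape[0] - 1)
        cols = (np.arange(p) * norm.shape[1] // p).clip(max=norm.shape[1] - 1)
        tiles_att.append(norm[np.ix_(rows, cols)])
    heat, _ = reassemble_average(tiles_att, origins, slide.image.shape[:2])
    return heat


def predict_slide(slide: WSIRecord, classifier, stats: NormalizationStats,
                  unets: dict[int, tuple], spec: PatchSpec,
                  bacm: BACM | None = None, threshold: float = 0.5,
                  rng: np.random.Generator | None = None) -> SlidePrediction:
    """Full slide pipeline: classify -> vote -> segment -> reassemble."""
    origins, probs = classify_patches(slide, classifier, stats, spec)
    slide_class = call_slide_class(probs)
    calls = probs.argmax(axis=1)
    mask, cnt = segment_and_reassemble(slide, slide_class, unets, spec,
                                       origins, calls, threshold)
    if bacm is not None:
        heat = attention_heatmap(slide, bacm, stats, spec, rng)
    else:
        heat = np.zeros(slide.image.shape[:2])
    return SlidePrediction(
        slide_id=slide.slide_id, origins=origins, probabilities=probs,
        slide_class=slide_class, lesion_mask=mask, heatmap=heat,
        covered=cnt > 0,
    )


def write_prediction(pred: SlidePrediction, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(pred.lesion_mask * 255).save(out / f"{pred.slide_id}_mask.png")
    heat8 = np.round(pred.heatmap * 255).astype(np.uint8)
    overlay = np.stack([heat8, np.zeros_like(heat8), 255 - heat8], axis=-1)
    Image.fromarray(overlay).save(out / f"{pred.slide_id}_heatmap.png")
    pd.DataFrame({
        "origin_row": [o[0] for o in pred.origins],
        "origin_col": [o[1] for o in pred.origins],
        **{f"p{c}": pred.probabilities[:, c]
           for c in range(pred.probabilities.shape[1])},
    }).to_csv(out / f"{pred.slide_id}_patches.csv", index=False)
    (out / f"{pred.slide_id}_verdict.json").write_text(json.dumps({
        "slide_id": pred.slide_id,
        "slide_class": int(pred.slide_class),
        "n_patches": len(pred.origins),
        "lesion_pixels": int(pred.lesion_mask.sum()),
    }, indent=2))
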