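"""Shared fixtures: a micro patch dataset small enough for second-scale
training tests."""

import numpy as np
import pytest

from macrespath import models


def make_color_patches(n_per_class: int, size: int = 32, n_classes: int = 4,
                       seed: int = 0):
    """Tiny labelled tiles: per-class RGB tint + pixel noise."""
    rng = np.random.default_rng(seed)
    tints = np.array([[220, 190, 205], [120, 80, 160],
                      [90, 140, 110], [150, 90, 70]], dtype=np.float64)
    X, y = [], []
    for c in range(n_classes):
        base = tints[c] + rng.normal(0, 25, (n_per_class, size, size, 3))
        X.append(np.clip(base, 0, 255).astype(np.uint8))
        y.append(np.full(n_per_class, c, dtype=np.int64))
    perm = rng.permutation(n_per_class * n_classes)
    return np.concatenate(X)[perm], np.concatenate(y)[perm]


@pytest.fixture(scope="session")
def micro_cfg():
    """Smallest classifier that still exercises every switch (32-px input)."""
    return models.miniature_config(spp_levels=(1,), input_size=32,
                                   n_attention_maps=2)


@pytest.fixture(scope="session")
def micro_data():
    return {
        "train": make_color_patches(16, seed=0),
        "val": make_color_patches(8, seed=1),
    }
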