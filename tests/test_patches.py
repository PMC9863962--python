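"""Tiling, coverage filtering, size cleaning and normalisation."""

import numpy as np
import pytest

from macrespath import patches, synthetic
from macrespath.patches import PatchSpec


def make_slide(mask: np.ndarray, label: int = 1, seed: int = 0) -> synthetic.WSIRecord:
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 255, mask.shape + (3,), dtype=np.uint8)
    return synthetic.WSIRecord(image=img, mask=mask.astype(np.uint8),
                               label=label, slide_id=f"t{seed}")


class TestEnumerateWindows:
    def test_1024_grid_has_nine_windows(self):
        spec = PatchSpec(patch_size=512, stride=256)
        origins = patches.enumerate_windows(1024, 1024, spec)
        assert origins == [(r, c) for r in (0, 256, 512) for c in (0, 256, 512)]

    def test_exact_fit_yields_single_origin(self):
        spec = PatchSpec(patch_size=512, stride=256)
        assert patches.enumerate_windows(512, 512, spec) == [(0, 0)]

    def test_undersized_image_warns_and_returns_empty(self):
        spec = PatchSpec(patch_size=512, stride=256)
        with pytest.warns(UserWarning, match="smaller than patch size"):
            assert patches.enumerate_windows(511, 1024, spec) == []

    def test_row_major_order_and_containment(self):
        spec = PatchSpec(patch_size=64, stride=48)
        origins = patches.enumerate_windows(200, 170, spec)
        assert origins == sorted(origins)
        assert all(r + 64 <= 200 and c + 64 <= 170 for r, c in origins)


class TestCoverageRule:
    def test_full_coverage_keeps_all_nine_windows(self):
        spec = PatchSpec(patch_size=512, stride=256)
        slide = make_slide(np.ones((1024, 1024)))
        assert len(patches.extract_patches(slide, spec)) == 9

    def test_exactly_three_quarters_is_discarded(self):
        # strict inequality: a window at exactly 0.75 coverage is dropped
        spec = PatchSpec(patch_size=64, stride=64)
        mask = np.zeros((64, 64))
        mask[:48, :] = 1  # exactly 3/4 of the window
        assert patches.extract_patches(make_slide(mask), spec) == []
        mask[48, 0] = 1   # one pixel above the threshold
        kept = patches.extract_patches(make_slide(mask), spec)
        assert len(kept) == 1 and kept[0].coverage > 0.75

    def test_random_masks_match_bruteforce_oracle(self):
        spec = PatchSpec(patch_size=64, stride=32)
        rng = np.random.default_rng(42)
        for _ in range(30):
            mask = (rng.random((160, 160)) < rng.uniform(0.6, 0.9)).astype(np.uint8)
            slide = make_slide(mask)
            kept = {p.origin for p in patches.extract_patches(slide, spec)}
            oracle = set()
            for r, c in patches.enumerate_windows(160, 160, spec):
                if mask[r:r + 64, c:c + 64].sum() / 64**2 > 0.75:
                    oracle.add((r, c))
            assert kept == oracle

    def test_patch_records_carry_origin_coverage_label(self):
        spec = PatchSpec(patch_size=64, stride=64)
        slide = make_slide(np.ones((128, 128)), label=3)
        recs = patches.extract_patches(slide, spec)
        assert {p.origin for p in recs} == {(0, 0), (0, 64), (64, 0), (64, 64)}
        assert all(p.label == 3 and p.coverage == 1.0 for p in recs)

    def test_shape_mismatch_rejected(self):
        slide = make_slide(np.ones((128, 128)))
        slide.mask = np.ones((64, 64), np.uint8)
        with pytest.raises(ValueError, match="mismatch"):
            patches.extract_patches(slide, PatchSpec(patch_size=64, stride=64))

    def test_origin_reconstruction_reproduces_source(self):
        spec = PatchSpec(patch_size=64, stride=32)
        slide = make_slide(np.ones((128, 128)))
        recon = np.zeros_like(slide.image)
        for p in patches.extract_patches(slide, spec):
            r, c = p.origin
            recon[r:r + 64, c:c + 64] = p.pixels
        assert np.array_equal(recon, slide.image)


class TestSizeFilter:
    def test_uniform_tile_compresses_below_threshold(self):
        spec = PatchSpec()  # 512 px, 330 KiB
        tile = patches.PatchRecord(np.full((512, 512, 3), 200, np.uint8),
                                   (0, 0), 1.0, 1, "s")
        keep, nbytes = patches.size_filter(tile, spec)
        assert not keep and 0 < nbytes < spec.min_encoded_bytes

    def test_noise_tile_encodes_above_threshold(self):
        spec = PatchSpec()
        rng = np.random.default_rng(0)
        tile = patches.PatchRecord(
            rng.integers(0, 255, (512, 512, 3), dtype=np.uint8), (0, 0), 1.0, 1, "s")
        keep, nbytes = patches.size_filter(tile, spec)
        assert keep and nbytes >= 330 * 1024

    def test_zero_threshold_keeps_everything(self):
        spec = PatchSpec(min_encoded_bytes=0)
        tile = patches.PatchRecord(np.zeros((512, 512, 3), np.uint8),
                                   (0, 0), 1.0, 1, "s")
        assert patches.size_filter(tile, spec)[0]

    def test_threshold_scales_with_patch_area(self):
        assert PatchSpec(patch_size=256, stride=256).scaled_min_bytes() == \
            round(330 * 1024 / 4)

    def test_count_conservation_through_pipeline(self):
        spec = PatchSpec(patch_size=64, stride=32, min_encoded_bytes=10_000)
        rng = np.random.default_rng(1)
        mask = (rng.random((160, 160)) < 0.85).astype(np.uint8)
        slide = make_slide(mask)
        n_windows = len(patches.enumerate_windows(160, 160, spec))
        extracted = patches.extract_patches(slide, spec)
        kept, _ = patches.clean_patches(extracted, spec)
        n_cov_drop = n_windows - len(extracted)
        n_size_drop = len(extracted) - len(kept)
        assert len(kept) + n_cov_drop + n_size_drop == n_windows


class TestNormalization:
    def test_known_moments_recovered(self):
        rng = np.random.default_rng(0)
        pix = rng.integers(0, 255, (20, 16, 16, 3)).astype(np.uint8)
        recs = [patches.PatchRecord(p, (0, 0), 1.0, 0, "s") for p in pix]
        stats = patches.fit_normalization(recs)
        flat = pix.reshape(-1, 3).astype(np.float64)
        assert np.allclose(stats.mean, flat.mean(axis=0))
        assert np.allclose(stats.std, flat.std(axis=0))
        normed = stats.apply(pix)
        assert np.abs(normed.reshape(-1, 3).mean(axis=0)).max() < 1e-4
        assert np.abs(normed.reshape(-1, 3).std(axis=0) - 1).max() < 1e-3

    def test_zero_variance_channel_rejected(self):
        recs = [patches.PatchRecord(np.full((8, 8, 3), 7, np.uint8),
                                    (0, 0), 1.0, 0, "s")] * 3
        with pytest.raises(ValueError, match="zero-variance"):
            patches.fit_normalization(recs)

    def test_stats_fitted_on_train_do_not_center_val(self):
        rng = np.random.default_rng(3)
        train = [patches.PatchRecord(
            rng.integers(0, 100, (8, 8, 3)).astype(np.uint8), (0, 0), 1.0, 0, "s")
            for _ in range(5)]
        val = rng.integers(150, 255, (5, 8, 8, 3)).astype(np.uint8)
        stats = patches.fit_normalization(train)
        assert np.abs(stats.apply(val).mean()) > 0.5  # no leakage: val not centered

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            patches.fit_normalization([])


class TestDatasetAssembly:
    def test_normal_slides_contribute_patches_via_region_override(self):
        cfg = synthetic.SyntheticConfig(image_size=128, n_slides_per_class=3,
                                        seed=2)
        splits = synthetic.generate_dataset(cfg)
        spec = PatchSpec(patch_size=64, stride=64, min_encoded_bytes=0)
        out = patches.extract_dataset_patches(splits, spec)
        train_labels = {p.label for p in out["train"]}
        assert 0 in train_labels
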