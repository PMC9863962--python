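"""Slide-level pipeline: voting, reassembly averaging, heatmaps."""

import numpy as np
import pytest

from macrespath import inference, models, synthetic
from macrespath.attention import BACM, attention_maps, normalize_attention
from macrespath.nn import Tensor
from macrespath.patches import NormalizationStats, PatchSpec


def identity_stats():
    return NormalizationStats(mean=np.zeros(3), std=np.ones(3),
                              computed_over=[])


class StubClassifier:
    """Always predicts the given class with high confidence."""

    def __init__(self, class_id: int, n_classes: int = 4):
        self.logits = np.full(n_classes, -5.0, dtype=np.float32)
        self.logits[class_id] = 5.0

    def eval(self):
        return self

    def __call__(self, x: Tensor) -> Tensor:
        return Tensor(np.tile(self.logits, (x.shape[0], 1)))


def make_slide(size=128, label=1, seed=0):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 255, (size, size, 3), dtype=np.uint8)
    mask = np.zeros((size, size), np.uint8)
    if label:
        mask[20:90, 30:100] = 1
    return synthetic.WSIRecord(image=img, mask=mask, label=label,
                               slide_id=f"s{seed}")


class TestClassifyPatches:
    def test_stub_classifier_calls_every_window_class_0(self):
        spec = PatchSpec(patch_size=32, stride=32)
        slide = make_slide(label=0)
        origins, probs = inference.classify_patches(
            slide, StubClassifier(0), identity_stats(), spec)
        assert len(origins) == 16
        assert (probs.argmax(axis=1) == 0).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_patch_count_equals_window_enumeration(self):
        spec = PatchSpec(patch_size=32, stride=16)
        slide = make_slide()
        from macrespath.patches import enumerate_windows

        origins, probs = inference.classify_patches(
            slide, StubClassifier(1), identity_stats(), spec)
        assert len(origins) == len(enumerate_windows(128, 128, spec))
        assert probs.shape[0] == len(origins)


class TestSlideVote:
    def test_majority_of_tumor_calls_wins(self):
        probs = np.zeros((9, 4))
        probs[:7, 1] = 0.9
        probs[:7, 0] = 0.1
        probs[7:, 0] = 0.9
        probs[7:, 1] = 0.1
        assert inference.call_slide_class(probs) == 1

    def test_all_normal_calls_yield_normal(self):
        probs = np.tile([0.9, 0.05, 0.03, 0.02], (5, 1))
        assert inference.call_slide_class(probs) == 0

    def test_tie_breaks_by_mean_probability(self):
        probs = np.zeros((8, 4))
        probs[:4, 1] = 0.9   # four confident class-1 calls
        probs[:4, 2] = 0.1
        probs[4:, 2] = 0.6   # four weak class-2 calls
        probs[4:, 1] = 0.4
        assert inference.call_slide_class(probs) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            inference.call_slide_class(np.empty((0, 4)))


class TestReassembly:
    def test_overlap_average_matches_accumulation_oracle(self):
        rng = np.random.default_rng(0)
        origins = [(0, 0), (0, 16), (16, 0), (8, 8), (16, 16)]
        tiles = [rng.random((32, 32)) for _ in origins]
        avg, cnt = inference.reassemble_average(tiles, origins, (48, 48))
        acc = np.zeros((48, 48))
        c = np.zeros((48, 48))
        for t, (r, co) in zip(tiles, origins):
            acc[r:r + 32, co:co + 32] += t
            c[r:r + 32, co:co + 32] += 1
        expect = np.divide(acc, c, out=np.zeros_like(acc), where=c > 0)
        assert np.array_equal(avg, expect)
        assert np.array_equal(cnt, c)

    def test_non_overlapping_grid_is_pure_tiling(self):
        rng = np.random.default_rng(1)
        tiles = [rng.random((16, 16)) for _ in range(4)]
        origins = [(0, 0), (0, 16), (16, 0), (16, 16)]
        avg, cnt = inference.reassemble_average(tiles, origins, (32, 32))
        assert (cnt == 1).all()
        for t, (r, c) in zip(tiles, origins):
            assert np.array_equal(avg[r:r + 16, c:c + 16], t)

    def test_uncovered_pixels_are_flagged(self):
        avg, cnt = inference.reassemble_average(
            [np.ones((16, 16))], [(0, 0)], (20, 20))
        assert cnt[18, 18] == 0 and avg[18, 18] == 0.0


class OracleSegmenter:
    """Stub network that reads the lesion signal from the red channel."""

    def eval(self):
        return self

    def __call__(self, x: Tensor) -> Tensor:
        logit = (x.data[..., 0] > 0.5) * 10.0 - 5.0
        return Tensor(logit[..., None])


class TestSegmentAndReassemble:
    def make_signal_slide(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[10:40, 20:50] = 1
        img = np.zeros((64, 64, 3), np.uint8)
        img[..., 0] = mask * 255
        return synthetic.WSIRecord(image=img, mask=mask, label=1,
                                   slide_id="sig")

    def test_oracle_segmenter_reconstructs_ground_truth(self):
        slide = self.make_signal_slide()
        spec = PatchSpec(patch_size=32, stride=16)
        from macrespath.patches import enumerate_windows

        origins = enumerate_windows(64, 64, spec)
        calls = np.ones(len(origins), dtype=int)
        unets = {1: (OracleSegmenter(), identity_stats())}
        mask, cnt = inference.segment_and_reassemble(
            slide, 1, unets, spec, origins, calls)
        assert (cnt > 0).all()
        assert np.array_equal(mask, slide.mask)

    def test_normal_called_windows_contribute_zeros(self):
        slide = self.make_signal_slide()
        spec = PatchSpec(patch_size=32, stride=32)
        origins = [(0, 0), (0, 32), (32, 0), (32, 32)]
        calls = np.zeros(4, dtype=int)
        unets = {1: (OracleSegmenter(), identity_stats())}
        mask, _ = inference.segment_and_reassemble(
            slide, 1, unets, spec, origins, calls)
        assert mask.sum() == 0

    def test_missing_network_rejected(self):
        slide = self.make_signal_slide()
        spec = PatchSpec(patch_size=32, stride=32)
        with pytest.raises(ValueError, match="no segmentation network"):
            inference.segment_and_reassemble(slide, 2, {}, spec,
                                             [(0, 0)], np.ones(1, int))

    def test_normal_slide_class_returns_empty_mask(self):
        slide = make_slide(label=0)
        spec = PatchSpec(patch_size=32, stride=32)
        mask, cnt = inference.segment_and_reassemble(
            slide, 0, {}, spec, [(0, 0)], np.zeros(1, int))
        assert mask.sum() == 0 and cnt.sum() == 0


@pytest.fixture(scope="module")
def bacm(micro_cfg):
    backbone = models.build_backbone(micro_cfg, seed=0)
    return BACM(backbone, n_maps=2, theta_c=0.5, crop_size=32, seed=0)


class TestHeatmap:
    def test_values_bounded_in_unit_interval(self, bacm):
        slide = make_slide(size=64)
        spec = PatchSpec(patch_size=32, stride=16)
        heat = inference.attention_heatmap(slide, bacm, identity_stats(), spec)
        assert heat.shape == (64, 64)
        assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_single_window_slide_equals_upsampled_attention(self, bacm):
        slide = make_slide(size=32)
        spec = PatchSpec(patch_size=32, stride=32)
        heat = inference.attention_heatmap(slide, bacm, identity_stats(), spec,
                                           rng=np.random.default_rng(5))
        pre = lambda b: (b.astype(np.float32))  # identity stats
        fmap = bacm.backbone.features(Tensor(pre(slide.image[None])))
        stack = attention_maps(fmap, bacm.head, np.random.default_rng(5))[0]
        norm, _ = normalize_attention(stack.maps[stack.selected_index])
        rows = (np.arange(32) * norm.shape[0] // 32).clip(max=norm.shape[0] - 1)
        expect = norm[np.ix_(rows, rows)]
        assert np.allclose(heat, expect)


class TestPredictSlide:
    def test_full_pipeline_with_stubs(self, tmp_path):
        slide = self_slide = TestSegmentAndReassemble().make_signal_slide()
        spec = PatchSpec(patch_size=32, stride=16)
        unets = {1: (OracleSegmenter(), identity_stats())}
        pred = inference.predict_slide(slide, StubClassifier(1),
                                       identity_stats(), unets, spec)
        assert pred.slide_class == 1
        assert np.array_equal(pred.lesion_mask, slide.mask)
        assert pred.covered.all()
        inference.write_prediction(pred, tmp_path)
        assert (tmp_path / "sig_verdict.json").exists()
        assert (tmp_path / "sig_mask.png").exists()
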