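"""Loss family: focal, temperature softmax, KD, label smoothing.

Every loss is checked against an independent scalar-arithmetic oracle
written directly in the tests.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macrespath import losses
from macrespath.losses import DistillParams, FocalParams
from macrespath.nn import Tensor


def np_softmax(z, t=1.0):
    z = np.asarray(z, dtype=np.float64) / t
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class TestFocal:
    def test_confident_correct_prediction_has_zero_loss(self):
        assert losses.focal_loss_pt(np.array([1.0])).item() == pytest.approx(0.0)

    def test_gamma_zero_alpha_one_reduces_to_cross_entropy(self):
        pt = np.array([0.3, 0.9, 0.5])
        out = losses.focal_loss_pt(pt, FocalParams(alpha=1.0, gamma=0.0)).item()
        assert out == pytest.approx((-np.log(pt)).mean(), abs=1e-6)

    def test_frozen_scalar_example(self):
        # -0.25 * (1 - 0.5)^2 * ln(0.5)
        out = losses.focal_loss_pt(np.array([0.5]),
                                   FocalParams(alpha=0.25, gamma=2.0)).item()
        assert out == pytest.approx(0.0433217, abs=1e-6)

    def test_zero_probability_is_clamped_finite(self):
        out = losses.focal_loss_pt(np.array([0.0]), FocalParams()).item()
        assert np.isfinite(out) and out > 0

    def test_from_logits_matches_manual_composition(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(8, 4))
        labels = rng.integers(0, 4, 8)
        out = losses.focal_loss(Tensor(logits), labels).item()
        p = np_softmax(logits)[np.arange(8), labels]
        oracle = (-0.25 * (1 - p) ** 2 * np.log(p)).mean()
        assert out == pytest.approx(oracle, abs=1e-6)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=16),
           st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_focal_never_exceeds_cross_entropy(self, pts, gamma):
        pt = np.array(pts)
        focal = losses.focal_loss_pt(pt, FocalParams(alpha=1.0, gamma=gamma)).item()
        ce = losses.focal_loss_pt(pt, FocalParams(alpha=1.0, gamma=0.0)).item()
        assert focal <= ce + 1e-6
        assert focal >= -1e-6

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FocalParams(gamma=-1.0)
        with pytest.raises(ValueError):
            FocalParams(alpha=0.0)


class TestTemperatureSoftmax:
    def test_equal_logits_give_uniform_for_any_temperature(self):
        for t in (0.5, 1.0, 4.0, 20.0):
            out = losses.softmax(Tensor(np.zeros((1, 4))), t).data
            assert np.allclose(out, 0.25, atol=1e-7)

    def test_temperature_one_is_ordinary_softmax(self):
        z = np.array([[0.3, -1.2, 2.0]])
        assert np.allclose(losses.softmax(Tensor(z), 1.0).data,
                           np_softmax(z), atol=1e-6)

    def test_frozen_two_logit_example(self):
        out = losses.soft_targets(np.array([[1.0, 2.0]]), 2.0)[0]
        assert out == pytest.approx([0.377540, 0.622459], abs=1e-6)

    def test_higher_temperature_flattens_distribution(self):
        z = np.array([[0.0, 3.0]])
        p1 = losses.soft_targets(z, 1.0)[0]
        p4 = losses.soft_targets(z, 4.0)[0]
        assert p4.max() < p1.max()

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        out = losses.softmax(Tensor(rng.normal(size=(32, 4)) * 10), 3.0).data
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            losses.softmax(Tensor(np.zeros((1, 2))), 0.0)


class TestKDLoss:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.logits = rng.normal(size=(6, 4))
        self.labels = rng.integers(0, 4, 6)
        self.shp = losses.softmax(Tensor(self.logits), 1.0)
        self.t = 4.0
        self.ssp = losses.softmax(Tensor(self.logits), self.t)
        self.tsl = np_softmax(rng.normal(size=(6, 4)), self.t)

    def test_mix_zero_is_pure_focal(self):
        out = losses.kd_loss(self.shp, self.ssp, self.tsl, self.labels,
                             DistillParams(temperature=self.t, mix=0.0)).item()
        focal = losses.focal_loss_pt(
            losses.true_class_prob(self.shp, self.labels)).item()
        assert out == pytest.approx(focal, abs=1e-6)

    def test_matching_distributions_zero_kl_term(self):
        tsl = np.asarray(self.ssp.data, dtype=np.float64)
        tsl /= tsl.sum(axis=1, keepdims=True)
        params = DistillParams(temperature=self.t, mix=0.7)
        out = losses.kd_loss(self.shp, self.ssp, tsl, self.labels, params).item()
        focal = losses.focal_loss_pt(
            losses.true_class_prob(self.shp, self.labels)).item()
        assert out == pytest.approx((1 - 0.7) * focal, abs=1e-5)

    def test_temperature_squared_scaling_of_kl_term(self):
        # a=1, T=2: loss = 4 * KL(TSL || SSP)
        params = DistillParams(temperature=2.0, mix=1.0)
        ssp2 = losses.softmax(Tensor(self.logits), 2.0)
        out = losses.kd_loss(self.shp, ssp2, self.tsl, self.labels, params).item()
        kl = (self.tsl * (np.log(self.tsl + 1e-12)
                          - np.log(ssp2.data + 1e-12))).sum(axis=1).mean()
        assert out == pytest.approx(4.0 * kl, abs=1e-5)

    def test_full_formula_matches_scalar_oracle(self):
        params = DistillParams(temperature=self.t, mix=0.7)
        out = losses.kd_loss(self.shp, self.ssp, self.tsl, self.labels,
                             params).item()
        p = self.shp.data[np.arange(6), self.labels].astype(np.float64)
        focal = (-0.25 * (1 - p) ** 2 * np.log(p)).mean()
        kl = (self.tsl * (np.log(self.tsl + 1e-12)
                          - np.log(self.ssp.data.astype(np.float64) + 1e-12))
              ).sum(axis=1).mean()
        oracle = 0.3 * focal + 0.7 * self.t**2 * kl
        assert out == pytest.approx(oracle, abs=1e-5)

    def test_unnormalized_inputs_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            losses.kd_loss(Tensor(self.logits), self.ssp, self.tsl,
                           self.labels, DistillParams())

    def test_param_bounds(self):
        with pytest.raises(ValueError):
            DistillParams(temperature=0.0)
        with pytest.raises(ValueError):
            DistillParams(mix=1.5)


class TestTotalLoss:
    def test_equal_weighting_arithmetic(self):
        out = losses.total_loss(Tensor(0.8), Tensor(0.6)).item()
        assert out == pytest.approx(0.7)

    def test_zero_attention_term_halves_kd(self):
        assert losses.total_loss(Tensor(0.8), Tensor(0.0)).item() == \
            pytest.approx(0.4)

    def test_degenerate_weights_recover_kd_loss(self):
        out = losses.total_loss(Tensor(0.8), Tensor(123.0), weights=(1.0, 0.0))
        assert out.item() == pytest.approx(0.8)


class TestLabelSmoothing:
    def test_zero_smoothing_is_cross_entropy(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(8, 4))
        labels = rng.integers(0, 4, 8)
        out = losses.label_smoothing_loss(Tensor(logits), labels, 0.0).item()
        ce = losses.cross_entropy(Tensor(logits), labels).item()
        assert out == pytest.approx(ce, abs=1e-5)

    def test_uniform_logits_cost_log_k_for_any_smoothing(self):
        logits = np.zeros((4, 4))
        labels = np.arange(4)
        for s in (0.0, 0.1, 0.5):
            out = losses.label_smoothing_loss(Tensor(logits), labels, s).item()
            assert out == pytest.approx(np.log(4), abs=1e-6)

    def test_confident_logits_pay_smoothing_penalty(self):
        logits = np.array([[30.0, 0.0, 0.0, 0.0]])
        labels = np.array([0])
        out_s = losses.label_smoothing_loss(Tensor(logits), labels, 0.1).item()
        out_0 = losses.label_smoothing_loss(Tensor(logits), labels, 0.0).item()
        assert out_0 == pytest.approx(0.0, abs=1e-5)
        # oracle: -(s/(K-1)) * sum(log p_other) at one-hot-confident logits
        p = np_softmax(logits)[0]
        oracle = -(0.9 * np.log(p[0] + 1e-12)
                   + (0.1 / 3) * np.log(p[1:] + 1e-12).sum())
        assert out_s == pytest.approx(oracle, abs=1e-4)
        assert out_s > 0.5

    def test_smoothing_bounds(self):
        with pytest.raises(ValueError, match="smoothing"):
            losses.label_smoothing_loss(Tensor(np.zeros((1, 4))),
                                        np.array([0]), 1.0)
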