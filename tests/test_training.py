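"""Cross-entropy loss values, optimiser protocol, convergence tracking."""

import numpy as np
import pytest

from ctcascade.nn import core
from ctcascade.nn.core import Tensor
from ctcascade.nn.layers import SGD
from ctcascade.segnet import SegNetConfig, build_segnet
from ctcascade.training import (FPNUNetSegmenter, TrainConfig, TrainHistory,
                                cross_entropy_loss, iou_of_history, train_segnet)

TINY = SegNetConfig(base_channels=4, fpn_channels=8)


class TestCrossEntropyValues:
    def test_uniform_prediction_is_log2(self):
        logits = np.zeros((2, 6, 6), dtype=np.float32)
        target = np.zeros((6, 6), dtype=int)
        assert cross_entropy_loss(logits, target) == pytest.approx(np.log(2), abs=1e-6)

    def test_quarter_three_quarter_distribution(self):
        # q = (0.25, 0.75), true class = tumor -> -ln 0.75
        logit_gap = np.log(3.0)  # softmax([0, ln 3]) = (0.25, 0.75)
        logits = np.stack([np.zeros((1, 1)), np.full((1, 1), logit_gap)]).astype(np.float32)
        assert cross_entropy_loss(logits, np.ones((1, 1), dtype=int)) == pytest.approx(
            -np.log(0.75), abs=1e-6)

    def test_perfect_prediction_tends_to_zero(self):
        logits = np.stack([np.full((3, 3), -20.0), np.full((3, 3), 20.0)]).astype(np.float32)
        assert cross_entropy_loss(logits, np.ones((3, 3), dtype=int)) < 1e-6

    def test_non_negative(self, rng):
        for _ in range(20):
            logits = rng.normal(size=(2, 4, 4)).astype(np.float32) * 5
            target = rng.integers(0, 2, (4, 4))
            assert cross_entropy_loss(logits, target) >= 0

    def test_shift_invariance(self, rng):
        logits = rng.normal(size=(2, 5, 5)).astype(np.float32)
        target = rng.integers(0, 2, (5, 5))
        shifted = logits + 3.7  # same constant added to every class channel
        assert cross_entropy_loss(logits, target) == pytest.approx(
            cross_entropy_loss(shifted, target), abs=1e-6)

    def test_target_out_of_range(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.zeros((2, 2, 2)), np.full((2, 2), 5))


def test_sgd_step_matches_finite_difference_gradient(rng):
    """With zero momentum and weight decay, one SGD step is vanilla gradient
    descent; the gradient itself is validated against central differences
    on a tiny model in float64."""
    with core.default_dtype(np.float64):
        model = build_segnet(TINY, seed=2)
        x = Tensor(rng.normal(size=(1, 3, 8, 8)))
        target = (rng.random((1, 8, 8)) < 0.3).astype(int)

        def loss_value():
            return float(core.softmax_cross_entropy(model(x), target).data)

        loss = core.softmax_cross_entropy(model(x), target)
        loss.backward()
        probe = model.parameters()[0]  # first conv weight
        grad = probe.grad.copy()
        eps = 1e-5
        flat = probe.data.reshape(-1)
        errors = []
        idx = np.argsort(-np.abs(grad.reshape(-1)))[:10]  # best-conditioned coords
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps; up = loss_value()
            flat[i] = orig - eps; down = loss_value()
            flat[i] = orig
            fd = (up - down) / (2 * eps)
            errors.append(abs(fd - grad.reshape(-1)[i])
                          / max(abs(fd), abs(grad.reshape(-1)[i])))
        assert max(errors) < 1e-3

        before = probe.data.copy()
        SGD([probe], lr=0.05).step()
        np.testing.assert_allclose(probe.data, before - 0.05 * grad, atol=1e-12)


def test_descent_after_one_small_step(rng):
    model = build_segnet(TINY, seed=4)
    x = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
    target = (rng.random((1, 8, 8)) < 0.4).astype(int)
    opt = SGD(model.parameters(), lr=1e-4)
    loss0 = core.softmax_cross_entropy(model(x), target)
    loss0.backward()
    opt.step()
    loss1 = core.softmax_cross_entropy(model(x), target)
    assert float(loss1.data) <= float(loss0.data) + 1e-6


@pytest.fixture(scope="module")
def crop_pairs(tumor_slices):
    from ctcascade.locator import crop_with_margin
    pairs = []
    for s in tumor_slices:
        for b in s.boxes:
            c = crop_with_margin(s, b, 10)
            pairs.append((c.image_crop, c.mask_crop))
    return pairs


class TestTrainSegnet:
    def test_overfit_descent(self, crop_pairs):
        model = build_segnet(TINY, seed=0)
        _, history = train_segnet(model, crop_pairs[:2],
                                  cfg=TrainConfig(epochs=30, batch_size=2, seed=0))
        assert history.records[-1][1] < history.records[0][1]

    def test_deterministic_loss_sequence(self, crop_pairs):
        cfg = TrainConfig(epochs=3, batch_size=2, seed=9)
        _, h1 = train_segnet(build_segnet(TINY, seed=1), crop_pairs[:4], cfg=cfg)
        _, h2 = train_segnet(build_segnet(TINY, seed=1), crop_pairs[:4], cfg=cfg)
        np.testing.assert_array_equal([r[:2] for r in h1.records],
                                      [r[:2] for r in h2.records])

    def test_eval_iou_recorded(self, crop_pairs):
        model = build_segnet(TINY, seed=0)
        _, history = train_segnet(model, crop_pairs[:4], eval_samples=crop_pairs[4:6],
                                  cfg=TrainConfig(epochs=2, batch_size=2, seed=0))
        curve = iou_of_history(history)
        assert len(curve) >= 2
        assert all(0.0 <= iou <= 1.0 for _, iou in curve)

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            train_segnet(build_segnet(TINY, seed=0), [])


def test_history_requires_increasing_iterations():
    h = TrainHistory()
    h.append(1, 0.5, 0.1)
    with pytest.raises(ValueError):
        h.append(1, 0.4, 0.2)


def test_iou_of_history_single_record_and_empty():
    h = TrainHistory()
    h.append(3, 0.2, 0.55)
    assert iou_of_history(h) == [(3, 0.55)]
    with pytest.raises(ValueError):
        iou_of_history(TrainHistory())


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lr=0)
    with pytest.raises(ValueError):
        TrainConfig(momentum=1.5)
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)


def test_estimator_get_set_params_round_trip():
    est = FPNUNetSegmenter(base_channels=4, epochs=1)
    params = est.get_params()
    assert params["base_channels"] == 4
    est.set_params(epochs=2)
    assert est.epochs == 2
    with pytest.raises(RuntimeError):
        est.predict([np.zeros((8, 8))])
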