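"""Stage A1: focus slicing, mosaic, detection contracts, crops, training."""

import numpy as np
import pytest

from ctcascade.io import BoundingBox, SliceSample, mask_to_boxes
from ctcascade.locator import (Detection, GridDetectorConfig, GridDetectorNet,
                               crop_with_margin, detect, focus_transform,
                               inverse_focus_transform, mosaic_augment,
                               non_max_suppression, oracle_detect, train_locator)


def make_sample(mask, image=None, volume_id="t", slice_index=0):
    mask = np.asarray(mask, dtype=np.uint8)
    if image is None:
        image = (mask * 200 + 30).astype(np.uint8)
    boxes = mask_to_boxes(mask)
    return SliceSample(image=image, mask=mask, boxes=boxes,
                       has_tumor=bool(boxes), volume_id=volume_id,
                       slice_index=slice_index)


class TestFocusTransform:
    def test_documented_parity_order(self):
        img = np.array([[[1.0, 2.0], [3.0, 4.0]]])  # [[a, b], [c, d]]
        out = focus_transform(img)
        assert out.shape == (4, 1, 1)
        np.testing.assert_array_equal(out.ravel(), [1, 2, 3, 4])

    def test_is_a_permutation(self, rng):
        img = rng.normal(size=(3, 8, 10))
        out = focus_transform(img)
        assert out.shape == (12, 4, 5)
        np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_inverse_recovers_input(self, rng):
        img = rng.normal(size=(2, 6, 8))
        np.testing.assert_array_equal(inverse_focus_transform(focus_transform(img)), img)

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError):
            focus_transform(np.zeros((1, 5, 4)))


class TestMosaic:
    def test_all_background_output_is_empty(self):
        bg = [make_sample(np.zeros((16, 16))) for _ in range(4)]
        out = mosaic_augment(bg, seed=0)
        assert not out.has_tumor and out.boxes == [] and not out.mask.any()

    def test_tumor_flag_matches_mask(self, tumor_slices, background_slices):
        out = mosaic_augment([tumor_slices[0], background_slices[0],
                              tumor_slices[1], background_slices[1]], seed=3)
        assert out.has_tumor == bool(out.mask.any())
        assert out.boxes == mask_to_boxes(out.mask)

    def test_requires_four_samples(self, tumor_slices):
        with pytest.raises(ValueError):
            mosaic_augment(tumor_slices[:3], seed=0)

    def test_deterministic(self, tumor_slices, background_slices):
        four = [tumor_slices[0], tumor_slices[1], background_slices[0],
                background_slices[1]]
        a = mosaic_augment(four, seed=9)
        b = mosaic_augment(four, seed=9)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)


class TestOracleDetect:
    def test_ground_truth_boxes_with_full_confidence(self):
        mask = np.zeros((16, 16))
        mask[2:5, 2:5] = 1
        mask[10:12, 10:14] = 1
        dets = oracle_detect(make_sample(mask))
        assert len(dets) == 2
        assert all(d.score == 1.0 for d in dets)
        assert [d.box for d in dets] == mask_to_boxes(mask)

    def test_background_slice_yields_nothing(self):
        assert oracle_detect(make_sample(np.zeros((8, 8)))) == []

    def test_missing_mask_rejected(self, tumor_slices):
        sample = tumor_slices[0]
        broken = SliceSample.__new__(SliceSample)
        broken.__dict__.update(vars(sample))
        broken.mask = None
        with pytest.raises(ValueError):
            oracle_detect(broken)


class TestCropWithMargin:
    def test_ten_pixel_expansion(self):
        # box (x 20-50, y 30-60) on 100x100, margin 10 -> window (10, 20, 60, 70)
        sample = make_sample(np.zeros((100, 100)), image=np.arange(10000).reshape(100, 100) % 256)
        box = BoundingBox(y_min=30, x_min=20, y_max=60, x_max=50)
        crop = crop_with_margin(sample, box, margin=10)
        assert crop.offset == (20, 10)
        assert crop.image_crop.shape == (50, 50)
        np.testing.assert_array_equal(crop.image_crop, sample.image[20:70, 10:60])

    def test_border_clamping(self):
        sample = make_sample(np.zeros((100, 100)))
        crop = crop_with_margin(sample, BoundingBox(0, 0, 5, 5), margin=10)
        assert crop.offset == (0, 0)
        assert crop.image_crop.shape == (15, 15)

    def test_zero_margin_is_box_exactly(self):
        mask = np.zeros((32, 32)); mask[8:12, 10:15] = 1
        sample = make_sample(mask)
        (box,) = sample.boxes
        crop = crop_with_margin(sample, box, margin=0)
        assert crop.image_crop.shape == (box.height, box.width)
        assert crop.mask_crop.all()

    def test_negative_margin_rejected(self, tumor_slices):
        with pytest.raises(ValueError):
            crop_with_margin(tumor_slices[0], tumor_slices[0].boxes[0], margin=-1)

    def test_paste_back_reproduces_mask_window(self, tumor_slices):
        for sample in tumor_slices[:3]:
            for box in sample.boxes:
                crop = crop_with_margin(sample, box, margin=10)
                canvas = np.zeros_like(sample.mask)
                y0, x0 = crop.offset
                h, w = crop.mask_crop.shape
                canvas[y0:y0 + h, x0:x0 + w] = crop.mask_crop
                window = np.zeros_like(sample.mask)
                window[y0:y0 + h, x0:x0 + w] = sample.mask[y0:y0 + h, x0:x0 + w]
                np.testing.assert_array_equal(canvas, window)


@pytest.fixture(scope="module")
def untrained_net():
    return GridDetectorNet(GridDetectorConfig(), seed=0)


class TestDetectContract:
    def test_unreachable_threshold_gives_nothing(self, untrained_net, tumor_slices):
        cfg = GridDetectorConfig(score_threshold=1.01)
        assert detect(untrained_net, tumor_slices[0], cfg) == []

    def test_scores_thresholded_and_sorted(self, untrained_net, tumor_slices):
        cfg = GridDetectorConfig(score_threshold=0.0)
        dets = detect(untrained_net, tumor_slices[0], cfg)
        scores = [d.score for d in dets]
        assert scores == sorted(scores, reverse=True)
        assert all(s >= 0.0 for s in scores)

    def test_boxes_clipped_to_slice(self, untrained_net, tumor_slices):
        h, w = tumor_slices[0].image.shape
        for d in detect(untrained_net, tumor_slices[0], GridDetectorConfig(score_threshold=0.0)):
            assert 0 <= d.box.x_min < d.box.x_max <= w
            assert 0 <= d.box.y_min < d.box.y_max <= h

    def test_image_smaller_than_cell_rejected(self, untrained_net):
        with pytest.raises(ValueError):
            detect(untrained_net, make_sample(np.zeros((4, 4))), GridDetectorConfig())

    def test_stride_channel_consistency_enforced(self):
        with pytest.raises(ValueError):
            GridDetectorConfig(grid_stride=16, channels=(8, 16), use_focus=False)


def test_nms_drops_overlapping_boxes():
    a = Detection(0.9, BoundingBox(0, 0, 10, 10))
    b = Detection(0.8, BoundingBox(1, 1, 11, 11))
    c = Detection(0.7, BoundingBox(20, 20, 30, 30))
    kept = non_max_suppression([a, b, c], iou_threshold=0.5)
    assert kept == [a, c]


class TestTrainLocator:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_locator([])

    def test_losses_finite_and_descending(self, tumor_slices, background_slices):
        pool = tumor_slices[:4] + background_slices[:4]
        net, history = train_locator(pool, epochs=8, seed=1, mosaic_prob=0.0)
        losses = [l for _, l in history.records]
        assert all(np.isfinite(losses))
        assert losses[-1] < losses[0]

    def test_overfit_detections_overlap_truth(self, tumor_slices, background_slices):
        pool = tumor_slices[:4] + background_slices[:4]
        net, _ = train_locator(pool, epochs=150, seed=1, mosaic_prob=0.0, lr=0.003)
        cfg = GridDetectorConfig()
        hits = 0
        for s in tumor_slices[:4]:
            dets = detect(net, s, cfg)
            assert dets, "trained detector missed a training tumor slice"
            if max(d.box.iou(b) for d in dets for b in s.boxes) > 0.3:
                hits += 1
        assert hits >= 4 * 0.9  # slice-level recall with localized boxes

    def test_deterministic_given_seed(self, tumor_slices, background_slices):
        pool = tumor_slices[:2] + background_slices[:2]
        _, h1 = train_locator(pool, epochs=3, seed=4)
        _, h2 = train_locator(pool, epochs=3, seed=4)
        assert h1.records == h2.records
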