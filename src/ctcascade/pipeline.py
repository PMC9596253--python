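"""Cascade orchestration: preprocess -> locate -> crop -> segment -> paste back.

For every axial slice the locator proposes confidence-scored boxes; each
box is expanded by the crop margin (default 10 px), the crop is padded to
the segmenter's divisibility requirement, segmented, unpadded and pasted
back at its offset. Predictions from overlapping crops are unioned
(logical OR) — deterministic and recall-preserving. Slices without
detections stay all-background.

The ablation harness retrains and evaluates the cascade over toggle
combinations of {shallow U-Net, localization stage, FPN skips}: the
"no-locator" configuration feeds whole padded slices to the segmenter,
"non-shallow" adds a fourth downsampling (classic U-Net depth), and
"no-FPN" uses plain encoder skips.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics as metrics_mod
from .io import CTVolume, LabelVolume, SliceSample, WindowSpec, extract_slices
from .locator import (GridDetector, GridDetectorConfig, crop_with_margin, detect,
                      oracle_detect)
from .nn.core import Tensor
from .segnet import SegNetConfig, predict_mask
from .training import FPNUNetSegmenter, prepare_input

__all__ = [
    "CascadeConfig", "VolumePrediction", "pad_to_multiple",
    "run_cascade", "evaluate_volumes", "run_ablation", "CascadeSegmenter",
]


@dataclass(frozen=True)
class CascadeConfig:
    window: WindowSpec = field(default_factory=WindowSpec)
    margin: int = 10
    detector_mode: str = "grid"  # or "oracle"
    detector: GridDetectorConfig = field(default_factory=GridDetectorConfig)
    segnet: SegNetConfig = field(default_factory=SegNetConfig)
    use_fpn: bool = True
    use_shallow: bool = True
    use_locator: bool = True

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.detector_mode not in ("grid", "oracle"):
            raise ValueError("detector_mode must be 'grid' or 'oracle'")

    @property
    def pad_multiple(self) -> int:
        return self.segnet.pad_multiple


@dataclass
class VolumePrediction:
    """Binary mask volume plus, per slice, which detections produced it."""

    mask_volume: np.ndarray
    provenance: list  # per slice: list of (score, box, crop_window)

    @property
    def tumor_slices(self) -> list:
        return [k for k in range(self.mask_volume.shape[0])
                if self.mask_volume[k].any()]


def pad_to_multiple(image: np.ndarray, multiple: int):
    """Reflect-pad bottom/right to the next multiple; returns the padded
    image and the (pad_bottom, pad_right) amounts for exact inversion."""
    if multiple < 1:
        raise ValueError("multiple must be >= 1")
    image = np.asarray(image)
    h, w = image.shape
    ph, pw = (-h) % multiple, (-w) % multiple
    if ph == 0 and pw == 0:
        return image, (0, 0)
    return np.pad(image, ((0, ph), (0, pw)), mode="reflect"), (ph, pw)


def _segment_crop(segmodel, crop_image: np.ndarray, multiple: int) -> np.ndarray:
    x, (h, w) = prepare_input(segmodel, crop_image)
    logits = segmodel(Tensor(x)).data[0]
    return predict_mask(logits)[:h, :w]


def run_cascade(volume: CTVolume, detector, segmodel, cfg: CascadeConfig,
                labels: LabelVolume | None = None) -> VolumePrediction:
    """Apply the full cascade to one volume.

    ``detector`` is a trained GridDetectorNet in grid mode and is ignored
    in oracle mode (which needs ``labels``). In the no-locator ablation the
    whole padded slice is segmented instead.
    """
    if cfg.detector_mode == "oracle" and labels is None:
        raise ValueError("oracle detector mode requires a label volume")
    if cfg.detector_mode == "grid" and cfg.use_locator and detector is None:
        raise ValueError("grid detector mode requires a trained detector")
    lbl = labels if labels is not None else LabelVolume(np.zeros_like(volume.data, dtype=np.uint8))
    samples = extract_slices(volume, lbl, cfg.window)
    out = np.zeros(volume.data.shape, dtype=np.uint8)
    provenance: list = []
    for k, sample in enumerate(samples):
        slice_prov = []
        if not cfg.use_locator:
            mask = _segment_crop(segmodel, sample.image, cfg.pad_multiple)
            out[k] = mask
            provenance.append([(1.0, None, (0, 0, *sample.image.shape))])
            continue
        if cfg.detector_mode == "oracle":
            dets = oracle_detect(sample)
        else:
            dets = detect(detector, sample, cfg.detector)
        for det in dets:
            crop = crop_with_margin(sample, det.box, cfg.margin)
            mask = _segment_crop(segmodel, crop.image_crop, cfg.pad_multiple)
            y0, x0 = crop.offset
            h, w = mask.shape
            out[k, y0:y0 + h, x0:x0 + w] |= mask
            slice_prov.append((det.score, det.box, (y0, x0, h, w)))
        provenance.append(slice_prov)
    return VolumePrediction(mask_volume=out, provenance=provenance)


def evaluate_volumes(predictions, label_volumes, only_detected: bool = False,
                     per_volume: bool = False) -> metrics_mod.MetricsReport:
    """Per-slice (default) or per-volume overlap metrics of cascade output.

    ``only_detected`` restricts scoring to slices where the cascade
    predicted something (the alternative reading of slice selection);
    the report's policy string records the mode used.
    """
    preds, truths, ids = [], [], []
    for v, (pred, lbl) in enumerate(zip(predictions, label_volumes)):
        pm = pred.mask_volume if isinstance(pred, VolumePrediction) else np.asarray(pred)
        lm = lbl.data if isinstance(lbl, LabelVolume) else np.asarray(lbl)
        if per_volume:
            preds.append(pm)
            truths.append(lm)
            ids.append(f"vol{v}")
            continue
        for k in range(pm.shape[0]):
            if only_detected and not pm[k].any():
                continue
            preds.append(pm[k])
            truths.append(lm[k])
            ids.append(f"vol{v}/slice{k}")
    policy = ("per-volume pooled" if per_volume else
              "per-slice, " + ("A1-detected slices only" if only_detected else "all slices")
              + ", nonempty ground truth")
    return metrics_mod.evaluate(preds, truths, sample_ids=ids, policy=policy,
                                per_volume=per_volume)


class CascadeSegmenter(BaseEstimator):
    """End-to-end estimator: fit on (volume, label) pairs, predict masks.

    The two stages are trained independently: the locator on every axial
    slice (tumor and background alike), the segmenter on margin-expanded
    crops around the ground-truth boxes — the same geometry the locator
    produces at inference. Toggles mirror the ablation axes: use_locator
    (whole-slice segmentation when off), use_shallow (depth 3 vs 4) and
    use_fpn (pyramid-fused vs plain skips).
    """

    def __init__(self, margin: int = 10, detector_mode: str = "grid",
                 use_fpn: bool = True, use_shallow: bool = True, use_locator: bool = True,
                 base_channels: int = 64, fpn_channels: int = 128,
                 fpn_fusion: str = "concat_into_skip",
                 window_level: float = 40.0, window_width: float = 400.0,
                 score_threshold: float = 0.25, detector_channels: tuple = (16, 32, 64),
                 nms_iou: float | None = None,
                 lr: float = 0.01, loc_lr: float = 0.001, momentum: float = 0.9,
                 weight_decay: float = 0.0005,
                 seg_epochs: int = 100, loc_epochs: int = 20, batch_size: int = 2,
                 eval_every: int | None = None, seed: int = 0):
        self.margin = margin
        self.detector_mode = detector_mode
        self.use_fpn = use_fpn
        self.use_shallow = use_shallow
        self.use_locator = use_locator
        self.base_channels = base_channels
        self.fpn_channels = fpn_channels
        self.fpn_fusion = fpn_fusion
        self.window_level = window_level
        self.window_width = window_width
        self.score_threshold = score_threshold
        self.detector_channels = detector_channels
        self.nms_iou = nms_iou
        self.lr = lr
        self.loc_lr = loc_lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.seg_epochs = seg_epochs
        self.loc_epochs = loc_epochs
        self.batch_size = batch_size
        self.eval_every = eval_every
        self.seed = seed

    # -- configuration plumbing ------------------------------------------

    def _window(self) -> WindowSpec:
        return WindowSpec(level=self.window_level, width=self.window_width)

    def _config(self) -> CascadeConfig:
        depth = 3 if self.use_shallow else 4
        seg = SegNetConfig(base_channels=self.base_channels, depth=depth,
                           fpn_channels=self.fpn_channels, fpn_fusion=self.fpn_fusion,
                           use_fpn=self.use_fpn)
        det = GridDetectorConfig(score_threshold=self.score_threshold,
                                 channels=tuple(self.detector_channels),
                                 nms_iou=self.nms_iou)
        return CascadeConfig(window=self._window(), margin=self.margin,
                             detector_mode=self.detector_mode, detector=det,
                             segnet=seg, use_fpn=self.use_fpn,
                             use_shallow=self.use_shallow, use_locator=self.use_locator)

    def _stage_seeds(self) -> tuple:
        state = np.random.SeedSequence(self.seed).generate_state(2, dtype=np.uint32)
        return tuple(int(s % (2 ** 31)) for s in state)

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, eval_set=None):
        """X: CTVolumes; y: LabelVolumes; optional eval_set = (X_val, y_val)
        used only to track the IoU convergence curve."""
        cfg = self._config()
        loc_seed, seg_seed = self._stage_seeds()
        all_slices: list[SliceSample] = []
        crops: list = []
        for vol, lbl in zip(X, y):
            samples = extract_slices(vol, lbl, cfg.window)
            all_slices.extend(samples)
            for s in samples:
                if not cfg.use_locator:
                    crops.append((s.image, s.mask))
                    continue
                for box in s.boxes:
                    c = crop_with_margin(s, box, cfg.margin)
                    crops.append((c.image_crop, c.mask_crop))
        if cfg.use_locator and not any(c[1].any() for c in crops):
            raise ValueError("no tumor-bearing slices in the training volumes")

        self.detector_ = None
        if cfg.use_locator and cfg.detector_mode == "grid":
            det = GridDetector(score_threshold=self.score_threshold,
                               channels=tuple(self.detector_channels),
                               nms_iou=self.nms_iou, lr=self.loc_lr, momentum=self.momentum,
                               weight_decay=self.weight_decay, epochs=self.loc_epochs,
                               seed=loc_seed)
            det.fit(all_slices)
            self.detector_ = det
            # A2 sees the crops A1 actually produces at inference: run the
            # trained detector over the training slices and add its crops,
            # so false-positive detections become negative training crops
            # the segmenter learns to reject. Ground-truth-box crops above
            # guarantee every lesion is represented even if A1 missed it.
            n_pos = len(crops)
            neg_rng = np.random.default_rng(seg_seed)
            neg_crops = []
            for s, dets in zip(all_slices, det.predict(all_slices)):
                for d in dets[:1]:
                    c = crop_with_margin(s, d.box, cfg.margin)
                    if not c.mask_crop.any():
                        neg_crops.append((c.image_crop, c.mask_crop))
            cap = max(4, n_pos // 2)
            if len(neg_crops) > cap:
                keep = neg_rng.choice(len(neg_crops), size=cap, replace=False)
                neg_crops = [neg_crops[int(i)] for i in sorted(keep)]
            crops.extend(neg_crops)

        eval_crops = None
        if eval_set is not None:
            eval_crops = []
            for vol, lbl in zip(*eval_set):
                for s in extract_slices(vol, lbl, cfg.window):
                    if not cfg.use_locator:
                        eval_crops.append((s.image, s.mask))
                    else:
                        for box in s.boxes:
                            c = crop_with_margin(s, box, cfg.margin)
                            eval_crops.append((c.image_crop, c.mask_crop))

        depth = 3 if self.use_shallow else 4
        seg = FPNUNetSegmenter(base_channels=self.base_channels, depth=depth,
                               fpn_channels=self.fpn_channels, fpn_fusion=self.fpn_fusion,
                               use_fpn=self.use_fpn, lr=self.lr, momentum=self.momentum,
                               weight_decay=self.weight_decay, epochs=self.seg_epochs,
                               batch_size=self.batch_size, seed=seg_seed,
                               eval_every=self.eval_every)
        seg.fit([c[0] for c in crops], [c[1] for c in crops], eval_set=eval_crops)
        self.segmenter_ = seg
        self.history_ = seg.history_
        return self

    def predict(self, X, labels=None):
        """Predict mask volumes; ``labels`` is only consulted in oracle
        detector mode. Returns a list of VolumePrediction."""
        if not hasattr(self, "segmenter_"):
            raise RuntimeError("cascade is not fitted; call fit first")
        cfg = self._config()
        out = []
        for i, vol in enumerate(X):
            lbl = labels[i] if labels is not None else None
            net = self.detector_.net_ if self.detector_ is not None else None
            out.append(run_cascade(vol, net, self.segmenter_.model_, cfg, labels=lbl))
        return out

    def score(self, X, y):
        """Mean held-out tumor-slice Dice (sklearn convention: higher is better)."""
        labels = y if self.detector_mode == "oracle" else None
        report = evaluate_volumes(self.predict(X, labels=labels), y)
        return report.aggregate["dice"]


TABLE_GRID = (
    {"use_shallow": False, "use_locator": False, "use_fpn": False},
    {"use_shallow": False, "use_locator": False, "use_fpn": True},
    {"use_shallow": True, "use_locator": False, "use_fpn": True},
    {"use_shallow": True, "use_locator": True, "use_fpn": True},
)


def run_ablation(train_set, test_set, grid=TABLE_GRID, seed: int = 0,
                 out_csv=None, **estimator_kwargs) -> list:
    """Train and evaluate the cascade for each toggle combination on the
    same split and seed; returns one row of toggles + Dice/Jaccard each."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty ablation grid")
    rows = []
    for toggles in grid:
        est = CascadeSegmenter(seed=seed, **toggles, **estimator_kwargs)
        est.fit(*train_set)
        report = evaluate_volumes(est.predict(test_set[0]), test_set[1])
        rows.append({**toggles,
                     "dice": report.aggregate["dice"],
                     "jaccard": report.aggregate["jaccard"]})
    if out_csv is not None:
        out_csv = Path(out_csv)
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows
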