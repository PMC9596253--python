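"""Stage A1: slice-level tumor localization and the coarse-segmentation crop.

The localizer scans axial slices, emits confidence-scored boxes, and each
box is expanded by a 10-pixel margin and cropped out as the input of the
fine segmenter. Two detectors sit behind the same interface:

* ``oracle_detect`` returns the ground-truth boxes with score 1.0 — a
  perfect-localizer mode that isolates the rest of the cascade in tests;
* a trainable anchor-free grid detector: a small convolutional backbone
  (optionally preceded by the lossless focus/space-to-depth slicing)
  downsamples the slice to a cell grid; a 1x1 head predicts, per cell, an
  objectness logit plus box center offsets and log-sizes. A cell is
  positive when a ground-truth box center falls in it. Training minimises
  binary cross-entropy on objectness plus squared error on the box
  parameters of positive cells, with mosaic augmentation mixed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .io import BoundingBox, SliceSample, mask_to_boxes, to_network_range
from .nn import core
from .nn.core import Tensor
from .nn.layers import Conv2d, ConvBlock, Module, SGD

__all__ = [
    "Detection", "CropResult", "GridDetectorConfig", "GridDetectorNet",
    "focus_transform", "inverse_focus_transform", "mosaic_augment",
    "detect", "oracle_detect", "crop_with_margin", "train_locator",
    "GridDetector", "non_max_suppression",
]


@dataclass(frozen=True)
class Detection:
    score: float
    box: BoundingBox

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class CropResult:
    image_crop: np.ndarray
    mask_crop: np.ndarray | None
    offset: tuple  # (y_min, x_min) of the crop in slice coordinates
    source: tuple  # (volume_id, slice_index)


@dataclass(frozen=True)
class GridDetectorConfig:
    """Grid geometry and backbone widths.

    Total downsampling must equal ``grid_stride``: the focus slicing
    contributes a factor 2 and each stage transition a further factor 2,
    so (2 if use_focus else 1) * 2**(len(channels) - 1) == grid_stride.
    The default score threshold is deliberately low: the cascade unions
    crops at paste-back, so the segmenter can reject a spurious crop but
    can never recover a slice the locator missed.
    """

    grid_stride: int = 8
    score_threshold: float = 0.25
    channels: tuple = (16, 32, 64)
    use_focus: bool = True
    nms_iou: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.score_threshold <= 1.01:
            raise ValueError("score_threshold must be in [0, 1] (or just above to disable)")
        down = (2 if self.use_focus else 1) * 2 ** (len(self.channels) - 1)
        if down != self.grid_stride:
            raise ValueError(
                f"backbone downsampling {down} != grid_stride {self.grid_stride}")


# ---------------------------------------------------------------------------
# focus (space-to-depth) slicing

def focus_transform(image: np.ndarray) -> np.ndarray:
    """Lossless space-to-depth: C x H x W -> 4C x H/2 x W/2.

    For each input channel c the four pixel parities become channels
    4c .. 4c+3 in the order (even row, even col), (even, odd),
    (odd, even), (odd, odd). A pure permutation of the values.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("expected a C x H x W array")
    c, h, w = image.shape
    if h % 2 or w % 2:
        raise ValueError("focus_transform requires even H and W")
    out = np.empty((4 * c, h // 2, w // 2), dtype=image.dtype)
    out[0::4] = image[:, 0::2, 0::2]
    out[1::4] = image[:, 0::2, 1::2]
    out[2::4] = image[:, 1::2, 0::2]
    out[3::4] = image[:, 1::2, 1::2]
    return out


def inverse_focus_transform(stacked: np.ndarray) -> np.ndarray:
    stacked = np.asarray(stacked)
    c4, h2, w2 = stacked.shape
    if c4 % 4:
        raise ValueError("channel count must be a multiple of 4")
    out = np.empty((c4 // 4, 2 * h2, 2 * w2), dtype=stacked.dtype)
    out[:, 0::2, 0::2] = stacked[0::4]
    out[:, 0::2, 1::2] = stacked[1::4]
    out[:, 1::2, 0::2] = stacked[2::4]
    out[:, 1::2, 1::2] = stacked[3::4]
    return out


def _focus_batch(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    out = np.empty((n, 4 * c, h // 2, w // 2), dtype=x.dtype)
    out[:, 0::4] = x[:, :, 0::2, 0::2]
    out[:, 1::4] = x[:, :, 0::2, 1::2]
    out[:, 2::4] = x[:, :, 1::2, 0::2]
    out[:, 3::4] = x[:, :, 1::2, 1::2]
    return out


# ---------------------------------------------------------------------------
# mosaic augmentation

def mosaic_augment(samples, out_size=None, seed: int = 0) -> SliceSample:
    """Compose four slice samples into one around a random center point.

    Each quadrant of the output receives a crop of the corresponding input
    taken at a random valid offset; masks are cropped identically and the
    output boxes are recomputed from the composed mask, so boxes clipped
    away vanish and partially clipped components shrink to tight boxes.
    """
    samples = list(samples)
    if len(samples) != 4:
        raise ValueError("mosaic_augment needs exactly 4 samples")
    rng = np.random.default_rng(seed)
    if out_size is None:
        out_size = samples[0].image.shape
    oh, ow = out_size
    cy = int(rng.integers(oh // 4, 3 * oh // 4 + 1))
    cx = int(rng.integers(ow // 4, 3 * ow // 4 + 1))
    image = np.zeros((oh, ow), dtype=samples[0].image.dtype)
    mask = np.zeros((oh, ow), dtype=np.uint8)
    regions = [(0, cy, 0, cx), (0, cy, cx, ow), (cy, oh, 0, cx), (cy, oh, cx, ow)]
    for sample, (y0, y1, x0, x1) in zip(samples, regions):
        h, w = y1 - y0, x1 - x0
        if h <= 0 or w <= 0:
            continue
        sh, sw = sample.image.shape
        if sh < h or sw < w:
            raise ValueError("source sample smaller than its mosaic quadrant")
        sy = int(rng.integers(0, sh - h + 1))
        sx = int(rng.integers(0, sw - w + 1))
        image[y0:y1, x0:x1] = sample.image[sy:sy + h, sx:sx + w]
        mask[y0:y1, x0:x1] = sample.mask[sy:sy + h, sx:sx + w]
    boxes = mask_to_boxes(mask)
    return SliceSample(image=image, mask=mask, boxes=boxes, has_tumor=bool(boxes),
                       volume_id="mosaic", slice_index=0)


# ---------------------------------------------------------------------------
# grid detector

class GridDetectorNet(Module):
    def __init__(self, config: GridDetectorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        in_ch = 12 if config.use_focus else 3
        self.blocks = []
        prev = in_ch
        for ch in config.channels:
            self.blocks.append(ConvBlock(prev, ch, rng))
            prev = ch
        self.head = Conv2d(prev, 5, 1, rng, std=0.01)  # objectness + (tx, ty, tw, th)

    def __call__(self, x: Tensor) -> Tensor:
        for i, block in enumerate(self.blocks):
            if i > 0:
                x = core.maxpool2x2(x)
            x = block(x)
        return self.head(x)


def _prepare_slices(images, stride: int, use_focus: bool) -> np.ndarray:
    """8-bit 2-D slices -> network input batch (padded to the grid)."""
    arrs = [np.asarray(im, dtype=np.float32) for im in images]
    hmax = max(a.shape[0] for a in arrs)
    wmax = max(a.shape[1] for a in arrs)
    hmax += (-hmax) % stride
    wmax += (-wmax) % stride
    x = np.zeros((len(arrs), 3, hmax, wmax), dtype=np.float32)
    for i, a in enumerate(arrs):
        x[i] = to_network_range(np.pad(a, ((0, hmax - a.shape[0]),
                                           (0, wmax - a.shape[1])),
                                       mode="reflect"))[None]
    return _focus_batch(x) if use_focus else x


def _decode_cells(raw: np.ndarray, stride: int, h: int, w: int,
                  threshold: float) -> list[Detection]:
    obj = core.sigmoid(raw[0])
    gy, gx = np.nonzero(obj >= threshold)
    detections = []
    for yy, xx in zip(gy, gx):
        tx, ty = core.sigmoid(raw[1, yy, xx]), core.sigmoid(raw[2, yy, xx])
        bw = float(np.exp(np.clip(raw[3, yy, xx], -6, 6))) * stride
        bh = float(np.exp(np.clip(raw[4, yy, xx], -6, 6))) * stride
        cx = (xx + tx) * stride
        cy = (yy + ty) * stride
        x0 = int(np.clip(round(cx - bw / 2), 0, w - 1))
        y0 = int(np.clip(round(cy - bh / 2), 0, h - 1))
        x1 = int(np.clip(round(cx + bw / 2), x0 + 1, w))
        y1 = int(np.clip(round(cy + bh / 2), y0 + 1, h))
        detections.append(Detection(score=float(obj[yy, xx]),
                                    box=BoundingBox(y_min=y0, x_min=x0, y_max=y1, x_max=x1)))
    return sorted(detections, key=lambda d: -d.score)


def non_max_suppression(detections, iou_threshold: float) -> list[Detection]:
    kept: list[Detection] = []
    for det in sorted(detections, key=lambda d: -d.score):
        if all(det.box.iou(k.box) < iou_threshold for k in kept):
            kept.append(det)
    return kept


def detect(net: GridDetectorNet, sample, config: GridDetectorConfig | None = None):
    """Run the grid detector on one SliceSample (or bare 2-D image).

    Returns detections with score >= config.score_threshold, boxes clipped
    to the slice, sorted by descending confidence.
    """
    config = config or net.config
    image = sample.image if isinstance(sample, SliceSample) else np.asarray(sample)
    h, w = image.shape
    if h < config.grid_stride or w < config.grid_stride:
        raise ValueError("image smaller than one grid cell")
    x = _prepare_slices([image], config.grid_stride, config.use_focus)
    raw = net(Tensor(x)).data[0]
    dets = _decode_cells(raw, config.grid_stride, h, w, config.score_threshold)
    if config.nms_iou is not None:
        dets = non_max_suppression(dets, config.nms_iou)
    return dets


def oracle_detect(sample: SliceSample) -> list[Detection]:
    """Ground-truth boxes with confidence 1.0 (perfect-localizer mode)."""
    if sample.mask is None:
        raise ValueError("oracle_detect needs a sample with a mask")
    return [Detection(score=1.0, box=b) for b in mask_to_boxes(sample.mask)]


def crop_with_margin(sample: SliceSample, box: BoundingBox, margin: int = 10) -> CropResult:
    """Expand the box by ``margin`` pixels on all four sides (clamped to the
    slice bounds) and crop image and mask identically."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    h, w = sample.image.shape
    if not (box.x_max <= w and box.y_max <= h):
        raise ValueError("box exceeds slice bounds")
    y0 = max(0, box.y_min - margin)
    x0 = max(0, box.x_min - margin)
    y1 = min(h, box.y_max + margin)
    x1 = min(w, box.x_max + margin)
    return CropResult(
        image_crop=sample.image[y0:y1, x0:x1],
        mask_crop=sample.mask[y0:y1, x0:x1] if sample.mask is not None else None,
        offset=(y0, x0),
        source=(sample.volume_id, sample.slice_index),
    )


# ---------------------------------------------------------------------------
# training

def _build_targets(samples, stride: int, gh: int, gw: int):
    n = len(samples)
    obj = np.zeros((n, 1, gh, gw), dtype=np.float32)
    reg = np.zeros((n, 4, gh, gw), dtype=np.float32)
    mask = np.zeros((n, 1, gh, gw), dtype=np.float32)
    for i, s in enumerate(samples):
        for b in s.boxes:
            cx = (b.x_min + b.x_max) / 2.0
            cy = (b.y_min + b.y_max) / 2.0
            gx = min(int(cx // stride), gw - 1)
            gy = min(int(cy // stride), gh - 1)
            obj[i, 0, gy, gx] = 1.0
            mask[i, 0, gy, gx] = 1.0
            reg[i, 0, gy, gx] = cx / stride - gx
            reg[i, 1, gy, gx] = cy / stride - gy
            reg[i, 2, gy, gx] = np.log(max(b.width, 1) / stride)
            reg[i, 3, gy, gx] = np.log(max(b.height, 1) / stride)
    return obj, reg, mask


@dataclass
class LocatorHistory:
    records: list = field(default_factory=list)  # (iteration, loss)


def train_locator(train_samples, config: GridDetectorConfig | None = None,
                  lr: float = 0.001, momentum: float = 0.9, weight_decay: float = 0.0005,
                  epochs: int = 20, batch_size: int = 8, seed: int = 0,
                  mosaic_prob: float = 0.5, pos_weight: float = 50.0):
    """Train the grid detector; returns (net, LocatorHistory).

    Each epoch shuffles the slice pool; with probability ``mosaic_prob`` a
    training example is replaced by a mosaic composition of four randomly
    drawn slices, which multiplies box/background variety. ``pos_weight``
    rebalances the objectness loss: positive cells are a fraction of a
    percent of the grid, and an unweighted loss collapses the head onto
    the base rate.
    """
    samples = list(train_samples)
    if not samples:
        raise ValueError("empty training set")
    config = config or GridDetectorConfig()
    rng = np.random.default_rng(seed)
    net = GridDetectorNet(config, seed=int(rng.integers(2 ** 31)))
    opt = SGD(net.parameters(), lr=lr, momentum=momentum, weight_decay=weight_decay)
    history = LocatorHistory()
    stride = config.grid_stride
    iteration = 0
    for _epoch in range(epochs):
        order = rng.permutation(len(samples))
        for start in range(0, len(samples), batch_size):
            batch = [samples[j] for j in order[start:start + batch_size]]
            batch = [
                mosaic_augment([samples[j] for j in rng.integers(0, len(samples), 4)],
                               out_size=s.image.shape, seed=int(rng.integers(2 ** 31)))
                if rng.random() < mosaic_prob else s
                for s in batch
            ]
            x = _prepare_slices([s.image for s in batch], stride, config.use_focus)
            gh, gw = x.shape[2] * (2 if config.use_focus else 1) // stride, \
                x.shape[3] * (2 if config.use_focus else 1) // stride
            obj_t, reg_t, pos = _build_targets(batch, stride, gh, gw)
            raw = net(Tensor(x))
            obj_loss = core.bce_with_logits(core.slice_channels(raw, 0, 1), obj_t,
                                            pos_weight=pos_weight)
            xy = core.sigmoid_t(core.slice_channels(raw, 1, 3))
            xy_loss = core.masked_l2(xy, reg_t[:, 0:2], np.repeat(pos, 2, axis=1))
            wh_loss = core.masked_l2(core.slice_channels(raw, 3, 5), reg_t[:, 2:4],
                                     np.repeat(pos, 2, axis=1))
            loss = core.add_scalars([obj_loss, xy_loss, wh_loss], [1.0, 2.0, 2.0])
            opt.zero_grad()
            loss.backward()
            opt.step()
            iteration += 1
            history.records.append((iteration, float(loss.data)))
    return net, history


class GridDetector(BaseEstimator):
    """sklearn-style estimator wrapping the trainable grid detector.

    fit(X) takes SliceSamples (boxes are the supervision; no separate y);
    predict(X) returns a list of Detection lists per slice.
    """

    def __init__(self, grid_stride: int = 8, score_threshold: float = 0.25,
                 channels: tuple = (16, 32, 64), use_focus: bool = True,
                 nms_iou: float | None = None, lr: float = 0.001, momentum: float = 0.9,
                 weight_decay: float = 0.0005, epochs: int = 20, batch_size: int = 8,
                 seed: int = 0, mosaic_prob: float = 0.5, pos_weight: float = 50.0):
        self.grid_stride = grid_stride
        self.score_threshold = score_threshold
        self.channels = channels
        self.use_focus = use_focus
        self.nms_iou = nms_iou
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.mosaic_prob = mosaic_prob
        self.pos_weight = pos_weight

    def _config(self) -> GridDetectorConfig:
        return GridDetectorConfig(grid_stride=self.grid_stride,
                                  score_threshold=self.score_threshold,
                                  channels=tuple(self.channels),
                                  use_focus=self.use_focus, nms_iou=self.nms_iou)

    def fit(self, X, y=None):
        net, history = train_locator(X, config=self._config(), lr=self.lr,
                                     momentum=self.momentum,
                                     weight_decay=self.weight_decay,
                                     epochs=self.epochs, batch_size=self.batch_size,
                                     seed=self.seed, mosaic_prob=self.mosaic_prob,
                                     pos_weight=self.pos_weight)
        self.net_ = net
        self.history_ = history
        return self

    def predict(self, X):
        if not hasattr(self, "net_"):
            raise RuntimeError("detector is not fitted; call fit first")
        cfg = self._config()
        return [detect(self.net_, s, cfg) for s in X]
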