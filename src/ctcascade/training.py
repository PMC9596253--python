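"""Loss, optimisation protocol and convergence tracking for the segmenter.

The loss is the unweighted per-pixel cross-entropy

    L(p, q) = - sum_i p(x_i) log q(x_i)

averaged over pixels, where p is the one-hot true distribution and q the
softmax of the network logits. Optimisation is small-batch SGD with
momentum 0.9, learning rate 0.01 and weight decay 5e-4 — constants kept
configurable but defaulted to the protocol the network was designed for.
Training records a history of (iteration, mean loss, evaluation IoU) so
convergence can be inspected; IoU here is the tumor-class Jaccard pooled
over the evaluation samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .nn import core
from .nn.core import Tensor
from .nn.layers import SGD
from .io import to_network_range
from .segnet import FPNUNet, SegNetConfig, build_segnet, predict_mask, tumor_probability

__all__ = [
    "TrainConfig", "TrainHistory", "cross_entropy_loss",
    "train_segnet", "iou_of_history", "FPNUNetSegmenter",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    epochs: int = 100
    batch_size: int = 2
    seed: int = 0
    eval_every: int | None = None  # iterations between IoU evaluations; None = per epoch
    class_weights: tuple | None = None  # optional (background, tumor) weighting

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    """(iteration, mean loss since last record, evaluation IoU) records."""

    records: list = field(default_factory=list)

    def append(self, iteration: int, loss: float, iou: float) -> None:
        if self.records and iteration <= self.records[-1][0]:
            raise ValueError("iteration indices must be strictly increasing")
        self.records.append((int(iteration), float(loss), float(iou)))

    def to_rows(self) -> list:
        return [{"iteration": it, "loss": lo, "iou": io} for it, lo, io in self.records]


def cross_entropy_loss(logits, target, class_weights=None) -> float:
    """Mean per-pixel cross-entropy of softmax(logits) against an integer
    class-index target; accepts (K, H, W) or (N, K, H, W) logits."""
    logits = np.asarray(logits, dtype=np.float32)
    target = np.asarray(target)
    if logits.ndim == 3:
        logits, target = logits[None], target[None]
    if target.shape != (logits.shape[0],) + logits.shape[2:]:
        raise ValueError("target shape does not match logits")
    return float(core.softmax_cross_entropy(Tensor(logits), target,
                                            class_weights=class_weights).data)


# ---------------------------------------------------------------------------
# data packing: crops of unequal size are padded (reflect) to one common
# shape divisible by the network's pad multiple; padded pixels get zero
# loss weight so they neither help nor hurt.

def _pack(images, masks, multiple: int):
    images = [np.asarray(im, dtype=np.float32) for im in images]
    hmax = max(im.shape[0] for im in images)
    wmax = max(im.shape[1] for im in images)
    hmax += (-hmax) % multiple
    wmax += (-wmax) % multiple
    n = len(images)
    x = np.zeros((n, 3, hmax, wmax), dtype=np.float32)
    y = np.zeros((n, hmax, wmax), dtype=np.int64)
    w = np.zeros((n, hmax, wmax), dtype=np.float32)
    for i, im in enumerate(images):
        h, wd = im.shape
        padded = to_network_range(np.pad(im, ((0, hmax - h), (0, wmax - wd)),
                                         mode="reflect"))
        x[i] = padded[None, :, :]  # broadcast to the 3-channel convention
        if masks is not None:
            y[i, :h, :wd] = np.asarray(masks[i])
        w[i, :h, :wd] = 1.0
    return x, y, w


def _pooled_iou(model: FPNUNet, images, masks, multiple: int) -> float:
    inter = union = 0
    for im, mk in zip(images, masks):
        pred = predict_on_image(model, im, multiple)
        mk = np.asarray(mk).astype(bool)
        pred = pred.astype(bool)
        inter += int(np.count_nonzero(pred & mk))
        union += int(np.count_nonzero(pred | mk))
    return inter / union if union else float("nan")


def _safe_pad(im: np.ndarray, ph: int, pw: int) -> np.ndarray:
    mode = "reflect" if ph < im.shape[0] and pw < im.shape[1] else "edge"
    return np.pad(im, ((0, ph), (0, pw)), mode=mode)


def prepare_input(model: FPNUNet, image) -> tuple:
    """Pad and normalise one 2-D 8-bit image into the network input batch.

    Images smaller than the canvas the model was trained on are padded up
    to that canvas, not merely to the divisibility multiple: the network's
    coarse (pyramid-top) features are sensitive to the canvas scale, so
    inference must present crops the way training did. Returns the
    (1, 3, H', W') batch and the original (h, w)."""
    im = np.asarray(image, dtype=np.float32)
    h, w = im.shape
    multiple = model.config.pad_multiple
    canvas = getattr(model, "canvas_hw", None)
    th = max(h + (-h) % multiple, canvas[0] if canvas else 0)
    tw = max(w + (-w) % multiple, canvas[1] if canvas else 0)
    padded = to_network_range(_safe_pad(im, th - h, tw - w))
    x = np.ascontiguousarray(np.broadcast_to(padded[None, None], (1, 3) + padded.shape))
    return x, (h, w)


def predict_on_image(model: FPNUNet, image, multiple: int | None = None) -> np.ndarray:
    """Pad-forward-unpad one 2-D 8-bit image; returns the binary mask."""
    x, (h, w) = prepare_input(model, image)
    logits = model(Tensor(x)).data[0]
    return predict_mask(logits)[:h, :w]


def train_segnet(model: FPNUNet, train_samples, eval_samples=None,
                 cfg: TrainConfig | None = None):
    """Train with momentum SGD; returns (model, TrainHistory).

    ``train_samples`` / ``eval_samples`` are sequences of (image, mask)
    pairs of 8-bit 2-D images. Shuffling and therefore the whole loss
    sequence are deterministic given cfg.seed.
    """
    cfg = cfg or TrainConfig()
    samples = list(train_samples)
    if not samples:
        raise ValueError("empty training set")
    eval_samples = list(eval_samples or [])
    multiple = model.config.pad_multiple
    x, y, w = _pack([s[0] for s in samples], [s[1] for s in samples], multiple)
    model.canvas_hw = (x.shape[2], x.shape[3])  # presentation scale for inference
    cw = np.asarray(cfg.class_weights, dtype=np.float32) if cfg.class_weights else None

    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    iteration = 0
    losses_since: list[float] = []

    def record():
        iou = (_pooled_iou(model, [s[0] for s in eval_samples],
                           [s[1] for s in eval_samples], multiple)
               if eval_samples else float("nan"))
        mean_loss = float(np.mean(losses_since)) if losses_since else float("nan")
        history.append(iteration, mean_loss, iou)
        losses_since.clear()

    if eval_samples:
        # record the untrained model's IoU so the curve shows the full rise
        record()

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        for start in range(0, len(samples), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model(Tensor(x[idx]))
            loss = core.softmax_cross_entropy(logits, y[idx], class_weights=cw,
                                              pixel_weights=w[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            iteration += 1
            losses_since.append(float(loss.data))
            if cfg.eval_every and iteration % cfg.eval_every == 0:
                record()
        if not cfg.eval_every:
            record()
    if losses_since:
        record()
    return model, history


def iou_of_history(history: TrainHistory) -> list:
    """(iteration, IoU) pairs for plotting the convergence curve."""
    if not history.records:
        raise ValueError("empty training history")
    return [(it, io) for it, _lo, io in history.records if not np.isnan(io)]


class FPNUNetSegmenter(BaseEstimator):
    """sklearn-style estimator around the FPN U-Net.

    fit(X, y) takes a sequence of 2-D 8-bit images and binary masks (the
    margin-expanded lesion crops in the cascade); predict(X) returns
    binary masks of the same sizes.
    """

    def __init__(self, base_channels: int = 64, depth: int = 3, n_classes: int = 2,
                 fpn_channels: int = 128, fpn_fusion: str = "concat_into_skip",
                 use_fpn: bool = True, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0005, epochs: int = 100, batch_size: int = 2,
                 seed: int = 0, eval_every: int | None = None,
                 class_weights: tuple | None = None):
        self.base_channels = base_channels
        self.depth = depth
        self.n_classes = n_classes
        self.fpn_channels = fpn_channels
        self.fpn_fusion = fpn_fusion
        self.use_fpn = use_fpn
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.eval_every = eval_every
        self.class_weights = class_weights

    def _net_config(self) -> SegNetConfig:
        return SegNetConfig(base_channels=self.base_channels, depth=self.depth,
                            n_classes=self.n_classes, fpn_channels=self.fpn_channels,
                            fpn_fusion=self.fpn_fusion, use_fpn=self.use_fpn)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, momentum=self.momentum,
                           weight_decay=self.weight_decay, epochs=self.epochs,
                           batch_size=self.batch_size, seed=self.seed,
                           eval_every=self.eval_every, class_weights=self.class_weights)

    def fit(self, X, y, eval_set=None):
        model = build_segnet(self._net_config(), seed=self.seed)
        samples = list(zip(X, y))
        model, history = train_segnet(model, samples, eval_samples=eval_set,
                                      cfg=self._train_config())
        self.model_ = model
        self.history_ = history
        return self

    def predict(self, X):
        self._check_fitted()
        return [predict_on_image(self.model_, im) for im in X]

    def predict_proba(self, X):
        self._check_fitted()
        out = []
        for im in X:
            x, (h, w) = prepare_input(self.model_, im)
            logits = self.model_(Tensor(x)).data
            out.append(tumor_probability(logits)[0, :h, :w])
        return out

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
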