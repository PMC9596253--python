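"""The fine-segmentation network: a shallow U-shaped encoder–decoder with
an embedded feature pyramid.

Architecture
------------
The encoder has ``depth + 1`` stages (default depth 3, i.e. one level
shallower than the classic 4-downsampling U-Net, to limit overfitting on
small lesion crops). Each stage applies two 3x3 convolutions with ReLU;
between stages a 2x2 max pooling with stride 2 halves the resolution and
the channel width doubles (64, 128, 256, 512 under defaults).

The encoder stage outputs form the bottom-up pathway of a feature pyramid:
each is projected to a common lateral width by a 1x1 convolution, and a
top-down pass repeatedly 2x-upsamples the coarser merged map and adds it
pixel-by-pixel to the next finer lateral map. The merged maps replace the
plain skip connections.

Each decoder step upsamples by linear interpolation, applies a 2x2
convolution that halves the channel count, fuses the corresponding pyramid
map (channel concatenation by default; addition via a 1x1 projection as an
option), and applies two 3x3 conv+ReLU. A final 1x1 convolution maps the
64-channel feature map to the class logits, so a 3 x H x W input yields an
n_classes x H x W output whenever H and W are divisible by 2**depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import core
from .nn.core import Tensor
from .nn.layers import Conv2d, ConvBlock, Module

__all__ = [
    "SegNetConfig", "FeaturePyramid", "FPNUNet",
    "build_segnet", "fpn_merge", "forward", "predict_mask",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class SegNetConfig:
    base_channels: int = 64
    depth: int = 3
    n_classes: int = 2
    fpn_channels: int = 128
    fpn_fusion: str = "concat_into_skip"  # or "add_into_skip"
    use_fpn: bool = True
    in_channels: int = 3

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1 or self.n_classes < 2:
            raise ValueError("invalid SegNetConfig")
        if self.fpn_fusion not in ("concat_into_skip", "add_into_skip"):
            raise ValueError("fpn_fusion must be concat_into_skip or add_into_skip")

    @property
    def stage_widths(self) -> tuple:
        return tuple(self.base_channels * 2 ** k for k in range(self.depth + 1))

    @property
    def pad_multiple(self) -> int:
        return 2 ** self.depth


@dataclass
class FeaturePyramid:
    """Merged multiscale maps, finest to coarsest, all at the lateral width."""

    levels: list

    def __post_init__(self):
        for fine, coarse in zip(self.levels, self.levels[1:]):
            fh, fw = fine.shape[2], fine.shape[3]
            ch, cw = coarse.shape[2], coarse.shape[3]
            if ch != fh // 2 or cw != fw // 2:
                raise ValueError("pyramid levels must halve in spatial size")


def _check_pyramid_progression(maps) -> None:
    for fine, coarse in zip(maps, maps[1:]):
        if coarse.shape[2] != fine.shape[2] // 2 or coarse.shape[3] != fine.shape[3] // 2:
            raise ValueError("encoder maps are not in a 2x spatial progression")


def fpn_merge(encoder_maps, fpn_channels: int | None = None,
              laterals: list | None = None, seed: int = 0) -> FeaturePyramid:
    """Lateral 1x1 projection + top-down 2x upsample and pixel-wise add.

    ``encoder_maps`` are ordered finest to coarsest. When ``laterals`` is
    not supplied, fresh 1x1 convolutions to ``fpn_channels`` are created
    (useful standalone; the network passes its own trained laterals).
    """
    maps = [m if isinstance(m, Tensor) else Tensor(m) for m in encoder_maps]
    if not maps:
        raise ValueError("fpn_merge needs at least one level")
    _check_pyramid_progression(maps)
    if laterals is None:
        if fpn_channels is None:
            raise ValueError("pass fpn_channels or laterals")
        rng = np.random.default_rng(seed)
        laterals = [Conv2d(m.shape[1], fpn_channels, 1, rng) for m in maps]
    projected = [lat(m) for lat, m in zip(laterals, maps)]
    merged = [projected[-1]]
    for finer in reversed(projected[:-1]):
        merged.append(core.add(finer, core.upsample2x(merged[-1])))
    merged.reverse()
    return FeaturePyramid(levels=merged)


class FPNUNet(Module):
    def __init__(self, config: SegNetConfig, seed: int = 0):
        self.config = config
        self.canvas_hw: tuple | None = None  # training canvas, set by the trainer
        rng = np.random.default_rng(seed)
        widths = config.stage_widths
        self.encoders = [ConvBlock(config.in_channels if k == 0 else widths[k - 1],
                                   widths[k], rng)
                         for k in range(config.depth + 1)]
        if config.use_fpn:
            self.laterals = [Conv2d(w, config.fpn_channels, 1, rng) for w in widths]
        else:
            self.laterals = []
        self.up_convs = []     # 2x2, halve channels after upsampling
        self.skip_projs = []   # only for add fusion
        self.dec_blocks = []
        for k in range(config.depth, 0, -1):
            self.up_convs.append(Conv2d(widths[k], widths[k - 1], 2, rng))
            skip_ch = config.fpn_channels if config.use_fpn else widths[k - 1]
            if config.fpn_fusion == "add_into_skip":
                self.skip_projs.append(Conv2d(skip_ch, widths[k - 1], 1, rng))
                self.dec_blocks.append(ConvBlock(widths[k - 1], widths[k - 1], rng))
            else:
                self.dec_blocks.append(ConvBlock(widths[k - 1] + skip_ch,
                                                 widths[k - 1], rng))
        self.head = Conv2d(widths[0], config.n_classes, 1, rng, std=0.01)

    def encode(self, x: Tensor) -> list:
        feats = []
        for k, block in enumerate(self.encoders):
            if k > 0:
                x = core.maxpool2x2(x)
            x = block(x)
            feats.append(x)
        return feats

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.config
        h, w = x.shape[2], x.shape[3]
        m = cfg.pad_multiple
        if h % m or w % m:
            raise ValueError(
                f"input {h}x{w} not divisible by {m}; pad first "
                "(see pipeline.pad_to_multiple)")
        feats = self.encode(x)
        if cfg.use_fpn:
            skips = fpn_merge(feats, laterals=self.laterals).levels[:cfg.depth]
        else:
            skips = feats[:cfg.depth]
        d = feats[-1]
        for i, k in enumerate(range(cfg.depth, 0, -1)):
            d = core.upsample2x(d)
            d = self.up_convs[i](d)
            skip = skips[k - 1]
            if cfg.fpn_fusion == "add_into_skip":
                d = core.add(d, self.skip_projs[i](skip))
            else:
                d = core.concat_channels(d, skip)
            d = self.dec_blocks[i](d)
        return self.head(d)


def build_segnet(config: SegNetConfig | None = None, seed: int = 0) -> FPNUNet:
    """Construct the network with deterministic, seeded initialisation."""
    return FPNUNet(config or SegNetConfig(), seed=seed)


def forward(model: FPNUNet, image: np.ndarray) -> np.ndarray:
    """Run one 3 x H x W image (or an N x 3 x H x W batch) through the
    network; returns logits with the same spatial size."""
    arr = np.asarray(image, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    out = model(Tensor(arr)).data
    return out[0] if single else out


def predict_mask(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the two channels; tumor where its probability
    exceeds 0.5 (an exact tie goes to background)."""
    logits = np.asarray(logits)
    single = logits.ndim == 3
    if single:
        logits = logits[None]
    if logits.shape[1] != 2:
        raise ValueError(f"expected 2 class channels, got {logits.shape[1]}")
    p = np.exp(core.log_softmax_channels(logits.astype(np.float32)))
    mask = (p[:, 1] > 0.5).astype(np.uint8)
    return mask[0] if single else mask


def tumor_probability(logits: np.ndarray) -> np.ndarray:
    logits = np.asarray(logits, dtype=np.float32)
    if logits.ndim == 3:
        logits = logits[None]
    return np.exp(core.log_softmax_channels(logits))[:, 1]


def save_checkpoint(model: FPNUNet, path) -> Path:
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    meta = dict(asdict(model.config))
    meta["canvas_hw"] = list(model.canvas_hw) if model.canvas_hw else None
    with open(path, "wb") as fh:
        np.savez(fh, config=json.dumps(meta), **arrays)
    return path


def load_checkpoint(path) -> FPNUNet:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["config"]))
        canvas = meta.pop("canvas_hw", None)
        model = FPNUNet(SegNetConfig(**meta), seed=0)
        model.canvas_hw = tuple(canvas) if canvas else None
        n = len(model.parameters())
        model.load_state_arrays([data[f"p{i}"] for i in range(n)])
    return model
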