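"""Volume I/O, intensity windowing, slice extraction and dataset splitting.

CT volumes are read from NIfTI with nibabel and held as plain numpy arrays
indexed (slice, row, col). Windowing maps a Hounsfield interval — center
``level``, extent ``width`` — linearly onto the output bit range, clipping
outside, which is how scanner consoles render soft tissue for display.

Axial slices are exported as 8-bit images (JPEG or PNG); ground-truth
masks are always written as PNG because lossy compression would corrupt
labels. Bounding boxes use 0-based (x, y) pixel coordinates with
half-open max edges, i.e. ``x_min <= x < x_max``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume", "LabelVolume", "WindowSpec", "BoundingBox", "SliceSample",
    "read_volume", "read_label_volume", "write_volume", "apply_window",
    "extract_slices", "mask_to_boxes", "export_slice", "split_dataset",
]


@dataclass
class CTVolume:
    """A 3-D intensity volume indexed (slice, row, col).

    ``spacing`` is (slice, row, col) voxel size in mm when known;
    ``affine`` is the 4x4 voxel-to-world transform from the NIfTI header.
    """

    data: np.ndarray
    spacing: tuple | None = None
    affine: np.ndarray | None = None
    volume_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise ValueError("every volume dimension must be >= 1")
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
                raise ValueError("spacing must be 3 positive lengths")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class LabelVolume:
    """Integer class labels voxel-aligned with a CTVolume.

    Any positive label is treated as tumor; multi-subtype annotations are
    collapsed to binary tumor/background on construction.
    """

    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if np.any(data < 0):
            raise ValueError("labels must be non-negative")
        self.data = (data > 0).astype(np.uint8)

    def check_paired(self, volume: CTVolume) -> None:
        if self.data.shape != volume.data.shape:
            raise ValueError(
                f"label shape {self.data.shape} != volume shape {volume.data.shape}")


@dataclass(frozen=True)
class WindowSpec:
    """Intensity window: center ``level``, extent ``width``, output depth.

    The default (level 40, width 400) is a standard abdominal soft-tissue
    window; both values are configurable because acquisition protocols vary.
    """

    level: float = 40.0
    width: float = 400.0
    out_depth: int = 8

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if self.out_depth not in (8, 16):
            raise ValueError("out_depth must be 8 or 16")

    @property
    def max_value(self) -> int:
        return (1 << self.out_depth) - 1


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based, half-open on the max edges."""

    y_min: int
    x_min: int
    y_max: int
    x_max: int

    def __post_init__(self):
        if not (0 <= self.x_min < self.x_max and 0 <= self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def iou(self, other: "BoundingBox") -> float:
        ix = max(0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union else 0.0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass
class SliceSample:
    """One axial slice: windowed image, binary mask, boxes, tumor flag."""

    image: np.ndarray
    mask: np.ndarray
    boxes: list[BoundingBox] = field(default_factory=list)
    has_tumor: bool = False
    volume_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if self.has_tumor != bool(self.mask.any()) or self.has_tumor != bool(self.boxes):
            raise ValueError("has_tumor flag inconsistent with mask/boxes")


# ---------------------------------------------------------------------------
# operations

def read_volume(path) -> CTVolume:
    """Read a NIfTI (.nii / .nii.gz) volume into (slice, row, col) order.

    nibabel loads NIfTI data in (i, j, k) fastest-first order; we move the
    last axis (the stack direction for axially acquired CT) to the front.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"not a readable NIfTI file: {path}") from exc
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0])) if len(zooms) == 3 else None
    return CTVolume(np.moveaxis(data, 2, 0), spacing=spacing,
                    affine=np.asarray(img.affine), volume_id=_stem(path))


def read_label_volume(path) -> LabelVolume:
    return LabelVolume(read_volume(path).data)


def write_volume(volume: CTVolume, path) -> Path:
    """Write a CTVolume back to NIfTI, inverting the axis convention."""
    path = Path(path)
    affine = volume.affine if volume.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.moveaxis(np.asarray(volume.data), 0, 2), affine), str(path))
    return path


def _stem(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def apply_window(volume: CTVolume, window: WindowSpec) -> CTVolume:
    """Map intensities through the window onto [0, 2^out_depth - 1]."""
    lo = window.level - window.width / 2.0
    scaled = np.clip((volume.data.astype(np.float64) - lo) / window.width, 0.0, 1.0)
    out = np.rint(scaled * window.max_value)
    dtype = np.uint8 if window.out_depth == 8 else np.uint16
    return CTVolume(out.astype(dtype), spacing=volume.spacing,
                    affine=volume.affine, volume_id=volume.volume_id)


def window_slice(slice2d: np.ndarray, window: WindowSpec) -> np.ndarray:
    lo = window.level - window.width / 2.0
    scaled = np.clip((np.asarray(slice2d, dtype=np.float64) - lo) / window.width, 0.0, 1.0)
    dtype = np.uint8 if window.out_depth == 8 else np.uint16
    return np.rint(scaled * window.max_value).astype(dtype)


def to_network_range(image) -> np.ndarray:
    """Map 8-bit intensities onto the symmetric network input range [-1, 1].

    Zero-centered inputs matter here: with all-positive inputs the first
    convolution's gradient components share signs, which in practice stalls
    the small networks this package trains from scratch.
    """
    return (np.asarray(image, dtype=np.float32) - 127.5) / 127.5


_CONN8 = np.ones((3, 3), dtype=int)


def mask_to_boxes(mask: np.ndarray) -> list[BoundingBox]:
    """Tight bounding boxes of the 8-connected foreground components,
    sorted by (y_min, x_min)."""
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    labeled, n = ndimage.label(mask, structure=_CONN8)
    boxes = []
    for sl in ndimage.find_objects(labeled):
        if sl is None:
            continue
        ys, xs = sl
        boxes.append(BoundingBox(y_min=int(ys.start), x_min=int(xs.start),
                                 y_max=int(ys.stop), x_max=int(xs.stop)))
    return sorted(boxes, key=lambda b: (b.y_min, b.x_min))


def extract_slices(volume: CTVolume, labels: LabelVolume,
                   window: WindowSpec | None = None) -> list[SliceSample]:
    """One SliceSample per axial index: windowed image, binary mask,
    component boxes, and the tumor-present flag."""
    labels.check_paired(volume)
    window = window or WindowSpec()
    windowed = apply_window(volume, window)
    samples = []
    for k in range(volume.n_slices):
        mask = labels.data[k]
        boxes = mask_to_boxes(mask)
        samples.append(SliceSample(
            image=windowed.data[k], mask=mask, boxes=boxes,
            has_tumor=bool(mask.any()), volume_id=volume.volume_id, slice_index=k))
    return samples


def export_slice(sample: SliceSample, out_dir, image_format: str = "png") -> tuple[Path, Path]:
    """Write the slice image (PNG or JPEG) and its mask (always PNG).

    Returns (image_path, mask_path). Filenames encode the volume id and
    slice index so exported datasets remain self-describing.
    """
    if image_format not in ("png", "jpg"):
        raise ValueError("image_format must be 'png' or 'jpg'")
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise IOError(f"not a writable directory: {out_dir}")
    stem = f"{sample.volume_id}_slice{sample.slice_index:04d}"
    image_path = out_dir / f"{stem}.{image_format}"
    mask_path = out_dir / f"{stem}_mask.png"
    iio.imwrite(image_path, sample.image.astype(np.uint8))
    iio.imwrite(mask_path, (sample.mask * 255).astype(np.uint8))
    return image_path, mask_path


def split_dataset(volume_ids, ratio: float = 0.8, seed: int = 0) -> tuple[list, list]:
    """Random patient-level split into (train, test).

    |train| = round(ratio * n); the split is deterministic given the seed
    and always disjoint/exhaustive. Splitting at the volume level keeps
    slices of one patient out of both sides.
    """
    ids = list(volume_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("volume ids must be unique")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def write_manifest(entries: list[dict], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(entries, indent=2))
    return path
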