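"""Synthetic CT-like phantoms: a soft-tissue organ ellipsoid containing
one or more small, bright, irregular tumor blobs.

The geometry mirrors what makes renal-tumor segmentation hard: the lesion
is tiny relative to the organ, sits at a variable position, has an
irregular boundary, and appears on only a minority of axial slices. The
generator makes no attempt at physical CT realism (no beam hardening or
reconstruction texture) — it produces a controlled contrast/noise setting
in which a segmentation cascade either works or does not.

Intensities are in arbitrary pre-window units chosen so that the default
abdominal window renders background, organ and tumor at distinct grey
levels: background 0–20, organ 80–120, tumor 140–180.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import CTVolume, LabelVolume, write_volume

__all__ = ["PhantomSpec", "GenerationError", "generate_phantom", "generate_dataset"]


class GenerationError(RuntimeError):
    """Raised when a tumor cannot be placed strictly inside the organ."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom volume.

    tumor_radius_range is the in-plane radius in pixels; the through-plane
    semi-axis is derived from ``tumor_slice_fraction`` so that roughly that
    fraction of axial slices contains tumor (a sphere of the same in-plane
    radius would span most of a thin stack). ``irregularity`` in [0, 1]
    scales a smooth random radial perturbation of the tumor boundary.
    """

    shape: tuple = (16, 64, 64)
    organ_intensity_range: tuple = (80.0, 120.0)
    tumor_intensity_range: tuple = (140.0, 180.0)
    background_intensity_range: tuple = (0.0, 20.0)
    tumor_radius_range: tuple = (3.0, 6.0)
    tumor_slice_fraction: float = 0.35
    noise_sd: float = 5.0
    irregularity: float = 0.3
    n_tumors: int = 1

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(d) < 1 for d in self.shape):
            raise ValueError("shape must be 3 positive integers")
        for name in ("organ_intensity_range", "tumor_intensity_range",
                     "background_intensity_range", "tumor_radius_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is not a valid interval")
        if not 0.0 < self.tumor_slice_fraction <= 1.0:
            raise ValueError("tumor_slice_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ValueError("irregularity must be in [0, 1]")
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be positive")


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    d2 = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    return d2 <= 1.0


def _perturbation_field(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean field in [-1, 1]: low-resolution noise upsampled
    with cubic interpolation — a cheap stand-in for low-order spherical
    harmonics of the boundary."""
    coarse = rng.normal(size=(4, 5, 5))
    zoom = [s / c for s, c in zip(shape, coarse.shape)]
    field = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    peak = np.abs(field).max()
    return field / peak if peak > 0 else field


def _tumor_mask(shape, center, r_inplane, r_z, irregularity, field) -> np.ndarray:
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    cz, cy, cx = center
    d = np.sqrt(((zz - cz) / r_z) ** 2 + ((yy - cy) / r_inplane) ** 2
                + ((xx - cx) / r_inplane) ** 2)
    # radial threshold wobbles around 1 with amplitude 0.35 * irregularity
    return d <= 1.0 + 0.35 * irregularity * field


def generate_phantom(spec: PhantomSpec, seed: int, return_info: bool = False):
    """Generate one phantom; deterministic given (spec, seed).

    Returns (CTVolume, LabelVolume) or, with ``return_info``, an extra dict
    carrying the drawn tumor centers/radii and the tumor slice indices —
    ground truth the tests use to validate the downstream pipeline.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = (int(d) for d in spec.shape)
    organ_semi = (max(1.0, 0.42 * nz), 0.36 * ny, 0.36 * nx)
    organ_center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    organ = _ellipsoid_mask(spec.shape, organ_center, organ_semi)

    r_z = max(1.0, spec.tumor_slice_fraction * nz / 2.0)
    tumors = np.zeros(spec.shape, dtype=bool)
    info = {"tumors": []}
    for _ in range(spec.n_tumors):
        r = rng.uniform(*spec.tumor_radius_range)
        if r >= min(organ_semi[1], organ_semi[2]) or r_z >= organ_semi[0] + 0.5:
            raise GenerationError("tumor radius too large for the organ")
        placed = False
        for _attempt in range(50):
            # sample the center inside a shrunken organ so the blob can fit
            fz = rng.uniform(-0.6, 0.6)
            fy = rng.uniform(-0.6, 0.6)
            fx = rng.uniform(-0.6, 0.6)
            center = (organ_center[0] + fz * (organ_semi[0] - r_z),
                      organ_center[1] + fy * (organ_semi[1] - r),
                      organ_center[2] + fx * (organ_semi[2] - r))
            field = _perturbation_field(spec.shape, rng)
            blob = _tumor_mask(spec.shape, center, r, r_z, spec.irregularity, field)
            if blob.any() and (blob <= organ).all() and not (blob & tumors).any():
                tumors |= blob
                info["tumors"].append({"center": [float(c) for c in center],
                                       "radius": float(r), "z_radius": float(r_z)})
                placed = True
                break
        if not placed:
            raise GenerationError("could not place a tumor strictly inside the organ")

    data = rng.uniform(*spec.background_intensity_range, size=spec.shape)
    data[organ] = rng.uniform(*spec.organ_intensity_range, size=int(organ.sum()))
    data[tumors] = rng.uniform(*spec.tumor_intensity_range, size=int(tumors.sum()))
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = CTVolume(data.astype(np.float32), spacing=(3.0, 1.0, 1.0))
    labels = LabelVolume(tumors.astype(np.uint8))
    if return_info:
        info["tumor_slices"] = sorted(int(k) for k in np.nonzero(tumors.any(axis=(1, 2)))[0])
        info["organ_center"] = [float(c) for c in organ_center]
        info["organ_semi_axes"] = [float(a) for a in organ_semi]
        return volume, labels, info
    return volume, labels


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Reproducible per-volume seeds from one master seed (all < 2^31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def generate_dataset(n_volumes: int, spec: PhantomSpec, seed: int, out_dir) -> Path:
    """Write ``n_volumes`` phantom image/label NIfTI pairs plus a JSON
    manifest; regenerating with the same master seed reproduces the files."""
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sub_seed in enumerate(derive_seeds(seed, n_volumes)):
        volume, labels, info = generate_phantom(spec, sub_seed, return_info=True)
        vid = f"phantom_{i:03d}"
        volume.volume_id = vid
        img_path = out_dir / f"{vid}.nii.gz"
        lbl_path = out_dir / f"{vid}_label.nii.gz"
        write_volume(volume, img_path)
        write_volume(CTVolume(labels.data, spacing=volume.spacing), lbl_path)
        entries.append({"volume_id": vid, "image": img_path.name, "label": lbl_path.name,
                        "seed": sub_seed, "tumor_slices": info["tumor_slices"]})
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(
        {"spec": asdict(spec), "master_seed": int(seed), "volumes": entries}, indent=2))
    return manifest
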