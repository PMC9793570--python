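"""Intensity and geometry operators between the two segmentation stages.

The trauma stage does not see the whole scan: the liver prediction is
dilated by a physical margin (default 5 mm), the scan is cropped to that
region, the crop's histogram is equalized, and the grayscale is inverted so
hypodense lesions become the brightest structures.  All geometry here is
anisotropy-aware — margins are physical distances, not voxel counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .core import BinaryMask, CTVolume, GeometryError, require_same_geometry

__all__ = [
    "RoiCrop",
    "dilate_mask_mm",
    "crop_to_mask",
    "crop_mask",
    "embed_mask",
    "equalize_histogram",
    "invert_grayscale",
]


@dataclass
class RoiCrop:
    """A subvolume plus the bookkeeping needed to re-embed results exactly.

    ``offset_voxels`` is the start index of the crop in the parent grid;
    ``parent_shape`` the parent grid shape.  The subvolume's origin is
    shifted accordingly so physical coordinates stay consistent.
    """

    subvolume: CTVolume
    offset_voxels: tuple[int, int, int]
    parent_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        off = tuple(int(o) for o in self.offset_voxels)
        if any(o < 0 for o in off):
            raise GeometryError("crop offset must be non-negative")
        if any(o + s > p for o, s, p in zip(off, self.subvolume.shape, self.parent_shape)):
            raise GeometryError("crop exceeds parent grid bounds")
        self.offset_voxels = off
        self.parent_shape = tuple(int(s) for s in self.parent_shape)


def dilate_mask_mm(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Dilate a mask by a physical margin (mm), anisotropy-aware.

    The output contains exactly the voxels whose center lies within
    Euclidean distance ``margin_mm`` of some input-true voxel center,
    computed with the per-axis spacing (an exact physical distance
    transform, not a fixed structuring element).
    """
    if margin_mm < 0:
        raise ValueError(f"margin_mm must be >= 0, got {margin_mm}")
    if mask.is_empty():
        warnings.warn("dilate_mask_mm: empty input mask returned unchanged")
        return mask
    if margin_mm == 0:
        return mask
    dist = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing_mm)
    return mask.with_values(dist <= margin_mm)


def crop_to_mask(volume: CTVolume, mask: BinaryMask) -> RoiCrop:
    """Crop the volume to the tight bounding box of the mask.

    Voxels inside the box but outside the mask keep their values; the
    recorded offset allows exact re-embedding.
    """
    require_same_geometry(volume, mask, "volume and mask")
    if mask.is_empty():
        raise GeometryError("cannot crop to an empty mask")
    idx = np.nonzero(mask.values)
    lo = [int(ax.min()) for ax in idx]
    hi = [int(ax.max()) + 1 for ax in idx]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_origin = tuple(
        volume.origin[ax] + lo[ax] * volume.spacing_mm[ax] for ax in range(3)
    )
    sub = CTVolume(volume.values[sl], volume.spacing_mm, sub_origin, volume.case_id)
    return RoiCrop(sub, tuple(lo), volume.shape)


def crop_mask(mask: BinaryMask, crop: RoiCrop) -> BinaryMask:
    """Restrict a full-grid mask to a crop's box (same geometry as the crop)."""
    if mask.shape != crop.parent_shape:
        raise GeometryError("mask does not match the crop's parent grid")
    sl = tuple(
        slice(o, o + s) for o, s in zip(crop.offset_voxels, crop.subvolume.shape)
    )
    return BinaryMask(mask.values[sl], mask.spacing_mm, crop.subvolume.origin)


def embed_mask(sub_mask: BinaryMask, crop: RoiCrop,
               parent_origin=(0.0, 0.0, 0.0)) -> BinaryMask:
    """Re-embed a crop-frame mask into the parent grid (zeros elsewhere)."""
    if sub_mask.shape != crop.subvolume.shape:
        raise GeometryError("sub-mask shape does not match the crop")
    full = np.zeros(crop.parent_shape, dtype=bool)
    sl = tuple(
        slice(o, o + s) for o, s in zip(crop.offset_voxels, sub_mask.shape)
    )
    full[sl] = sub_mask.values
    return BinaryMask(full, sub_mask.spacing_mm, parent_origin)


def equalize_histogram(crop: RoiCrop, n_bins: int = 256,
                       within_mask: BinaryMask | None = None) -> RoiCrop:
    """Histogram-equalize a crop to [0, 1].

    The transform is a monotone non-decreasing remap of intensities (the
    empirical CDF).  When ``within_mask`` is given the mapping is fit on the
    masked voxels only — by default the dilated liver mask, so that
    background outside the organ does not dilute parenchyma/lesion contrast
    — and applied to every voxel in the crop.  Constant input maps to a
    constant without failure.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    img = crop.subvolume.values.astype(np.float64)
    mask_arr = None
    if within_mask is not None:
        if within_mask.shape != crop.subvolume.shape:
            raise GeometryError("within_mask must share the crop's grid")
        mask_arr = within_mask.values
        if not mask_arr.any():
            mask_arr = None
    if np.ptp(img) == 0:
        out = np.ones_like(img)
    elif mask_arr is not None:
        out = exposure.equalize_hist(img, nbins=n_bins, mask=mask_arr)
    else:
        out = exposure.equalize_hist(img, nbins=n_bins)
    out = np.clip(out, 0.0, 1.0)
    return RoiCrop(crop.subvolume.with_values(out), crop.offset_voxels, crop.parent_shape)


def invert_grayscale(crop: RoiCrop) -> RoiCrop:
    """Invert a normalized crop voxel-wise: v -> 1 - v.

    Requires intensities in [0, 1] (i.e. run after equalization or
    normalization); hypodense trauma becomes hyperintense.
    """
    v = crop.subvolume.values
    if v.min() < -1e-6 or v.max() > 1 + 1e-6:
        raise ValueError("invert_grayscale requires intensities in [0, 1]")
    out = 1.0 - np.clip(v, 0.0, 1.0)
    return RoiCrop(crop.subvolume.with_values(out), crop.offset_voxels, crop.parent_shape)
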