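"""Volume and mask I/O: NIfTI files, DICOM series directories, voxel geometry.

Physical volumes are derived from voxel spacing carried in the file headers
(pixel spacing and slice spacing for DICOM, the affine zooms for NIfTI), which
is the sole source of the per-voxel volume used downstream.

Orientation convention: NIfTI input is reoriented to the closest RAS+
(canonical) orientation on read, so all in-memory grids agree on axis order
regardless of how the file was stored.  DICOM series are stacked along the
slice normal in ascending slice position, with array axes (row, column,
slice).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .core import BinaryMask, CTVolume, GeometryError

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "unit_voxel_volume_ml",
]


def unit_voxel_volume_ml(spacing_mm) -> float:
    """Physical volume of one voxel in millilitres.

    The product of the per-axis spacings gives the voxel volume in mm^3;
    1 ml = 1000 mm^3.
    """
    sp = [float(s) for s in spacing_mm]
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise GeometryError(f"spacing must be 3 positive values, got {spacing_mm}")
    return sp[0] * sp[1] * sp[2] / 1000.0


def _affine(spacing_mm, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    aff[:3, 3] = origin
    return aff


def _from_nifti(img) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D NIfTI grid, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise GeometryError(f"nonpositive voxel spacing in NIfTI header: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, zooms, origin


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, tuple, tuple]:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR, notes)
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise GeometryError(f"no DICOM image slices found in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) > 1:
        raise GeometryError(f"directory {directory} mixes {len(uids)} DICOM series")

    ref = slices[0]
    if not hasattr(ref, "PixelSpacing"):
        raise GeometryError(
            "DICOM series lacks PixelSpacing; voxel volume cannot be computed"
        )
    row_sp, col_sp = (float(v) for v in ref.PixelSpacing)

    # Sort by position along the slice normal (fall back to InstanceNumber).
    if hasattr(ref, "ImagePositionPatient") and hasattr(ref, "ImageOrientationPatient"):
        iop = np.asarray([float(v) for v in ref.ImageOrientationPatient])
        normal = np.cross(iop[:3], iop[3:])
        key = lambda ds: float(np.dot(normal, [float(v) for v in ds.ImagePositionPatient]))
    else:
        key = lambda ds: int(getattr(ds, "InstanceNumber", 0))
    slices.sort(key=key)

    if len(slices) > 1 and hasattr(ref, "ImagePositionPatient"):
        zs = np.array([key(ds) for ds in slices], dtype=float)
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise GeometryError("duplicate or non-monotone DICOM slice positions")
        slice_sp = float(np.mean(dz))
    else:
        slice_sp = float(getattr(ref, "SliceThickness", 0.0))
    if slice_sp <= 0 or row_sp <= 0 or col_sp <= 0:
        raise GeometryError(
            f"nonpositive DICOM spacing (row={row_sp}, col={col_sp}, slice={slice_sp})"
        )

    arrs = []
    for ds in slices:
        a = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        arrs.append(a * slope + inter)
    data = np.stack(arrs, axis=-1)  # (row, col, slice)
    origin = (0.0, 0.0, 0.0)
    if hasattr(slices[0], "ImagePositionPatient"):
        origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return data, (row_sp, col_sp, slice_sp), origin


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from a NIfTI file or a directory of DICOM slices.

    Intensity values pass through unchanged (DICOM rescale slope/intercept
    applied).  Raises :class:`GeometryError` on mixed series, missing or
    nonpositive spacing metadata.
    """
    path = Path(path)
    if path.is_dir():
        data, spacing, origin = _read_dicom_series(path)
    else:
        data, spacing, origin = _from_nifti(nib.load(str(path)))
    case_id = path.name.removesuffix(".gz").removesuffix(".nii")
    return CTVolume(data.astype(np.float32), spacing, origin, case_id=case_id)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask from NIfTI; voxels binarize at > 0.5."""
    data, spacing, origin = _from_nifti(nib.load(str(Path(path))))
    return BinaryMask(data > 0.5, spacing, origin)


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing_mm, volume.origin))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as a 0/1 uint8 NIfTI with spacing in the header."""
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing_mm, mask.origin))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))
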