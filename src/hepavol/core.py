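"""Core in-memory containers for CT volumes and binary masks.

The canonical in-memory layout is a 3D array indexed ``(x, y, z)`` with a
physical voxel size per axis in millimetres and a physical origin.  Voxel
``(i, j, k)`` has its *center* at ``origin + (i + 0.5, j + 0.5, k + 0.5) *
spacing_mm`` — the half-voxel convention matters for phantom voxelization
and for physical-distance morphology, and is used consistently throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["CTVolume", "BinaryMask", "GeometryError", "voxel_center_coords"]


class GeometryError(ValueError):
    """Raised when volumes/masks disagree on grid geometry or a geometric
    precondition (e.g. an object exceeding grid bounds) is violated."""


def _as_spacing(spacing_mm) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing_mm)
    if len(sp) != 3:
        raise GeometryError(f"spacing_mm must have 3 entries, got {len(sp)}")
    if any(s <= 0 for s in sp):
        raise GeometryError(f"spacing_mm must be positive, got {sp}")
    return sp


def _as_origin(origin) -> tuple[float, float, float]:
    org = tuple(float(s) for s in origin)
    if len(org) != 3:
        raise GeometryError(f"origin must have 3 entries, got {len(org)}")
    return org


@dataclass
class CTVolume:
    """A 3D scalar attenuation grid with physical voxel geometry.

    Parameters
    ----------
    values
        3D array of attenuation values (HU-like units); stored as float32.
    spacing_mm
        Per-axis voxel size in millimetres, all positive.
    origin
        Physical offset of the grid corner in millimetres.
    case_id
        Free-form identifier carried through the pipeline.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    case_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.size == 0:
            raise GeometryError("CTVolume requires a non-empty 3D grid")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_geometry(self, other: "CTVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray) -> "CTVolume":
        return replace(self, values=np.asarray(values, dtype=np.float32))


@dataclass
class BinaryMask:
    """A 3D boolean grid sharing a :class:`CTVolume`'s geometry."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) > 0.5
        if self.values.ndim != 3 or self.values.size == 0:
            raise GeometryError("BinaryMask requires a non-empty 3D grid")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(np.count_nonzero(self.values))

    def is_empty(self) -> bool:
        return not self.values.any()

    def same_geometry(self, other: "CTVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return replace(self, values=np.asarray(values) > 0.5)


def require_same_geometry(a, b, what: str = "operands") -> None:
    if not a.same_geometry(b):
        raise GeometryError(f"{what} must share grid shape, spacing and origin")


def voxel_center_coords(shape, spacing_mm, origin=(0.0, 0.0, 0.0)):
    """Physical coordinates (mm) of voxel centers, one 1D array per axis."""
    return [
        origin[ax] + (np.arange(shape[ax], dtype=np.float64) + 0.5) * spacing_mm[ax]
        for ax in range(3)
    ]
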