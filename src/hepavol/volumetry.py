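"""Voxel volumetry and the liver parenchymal disruption index (LPDI).

A structure's volume is estimated as (number of true voxels) x (unit voxel
volume from spacing metadata).  The LPDI is the ratio of trauma volume to
whole-liver volume expressed as a percentage:

    LPDI = 100 * V(trauma) / V(liver)
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import BinaryMask
from .io import unit_voxel_volume_ml

__all__ = ["VolumetryResult", "mask_volume_ml", "compute_lpdi"]


@dataclass(frozen=True)
class VolumetryResult:
    """Per-case volumetry: liver volume, trauma volume (ml) and LPDI (%)."""

    case_id: str
    liver_volume_ml: float
    trauma_volume_ml: float
    lpdi_pct: float

    def __post_init__(self) -> None:
        if self.liver_volume_ml < 0 or self.trauma_volume_ml < 0:
            raise ValueError("volumes must be non-negative")


def mask_volume_ml(mask: BinaryMask) -> float:
    """Physical volume of a mask: true-voxel count x unit voxel volume."""
    return mask.count() * unit_voxel_volume_ml(mask.spacing_mm)


def compute_lpdi(trauma_volume_ml: float, liver_volume_ml: float) -> float:
    """LPDI in percent.  A nonpositive liver volume signals failed liver
    segmentation upstream and is rejected."""
    if liver_volume_ml <= 0:
        raise ValueError(
            f"liver volume must be positive (got {liver_volume_ml} ml); "
            "upstream liver segmentation failed"
        )
    if trauma_volume_ml < 0:
        raise ValueError("trauma volume must be non-negative")
    return 100.0 * trauma_volume_ml / liver_volume_ml
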