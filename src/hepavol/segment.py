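"""Segmentation backends for the cascade.

A backend is any callable mapping a :class:`CTVolume` to a
:class:`BinaryMask` on the same grid.  Three are provided:

* :class:`ModelSegmenter` — a trained residual U-Net with sliding-window
  inference (the deep-learning path);
* :class:`ThresholdSegmenter` — a deterministic intensity band, an oracle
  backend that makes the cascade, volumetry and statistics testable without
  any training;
* :class:`OracleSegmenter` — returns a stored reference mask (restricted to
  the grid it is asked about), for ground-truth passthrough checks.
"""

from __future__ import annotations


from .core import BinaryMask, CTVolume, GeometryError
from .nn.infer import predict_mask
from .nn.model import ResidualUNet3D

__all__ = ["threshold_segmenter", "ThresholdSegmenter", "ModelSegmenter",
           "OracleSegmenter"]


def threshold_segmenter(volume: CTVolume, low: float, high: float) -> BinaryMask:
    """Voxels with value in [low, high] set true."""
    if not low < high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    values = (volume.values >= low) & (volume.values <= high)
    return BinaryMask(values, volume.spacing_mm, volume.origin)


class ThresholdSegmenter:
    def __init__(self, low: float, high: float):
        if not low < high:
            raise ValueError(f"need low < high, got [{low}, {high}]")
        self.low, self.high = float(low), float(high)

    def __call__(self, volume: CTVolume) -> BinaryMask:
        return threshold_segmenter(volume, self.low, self.high)


class ModelSegmenter:
    def __init__(self, model: ResidualUNet3D, threshold: float = 0.5):
        self.model = model
        self.threshold = threshold

    def __call__(self, volume: CTVolume) -> BinaryMask:
        return predict_mask(self.model, volume, self.threshold)


class OracleSegmenter:
    """Replays a known reference mask, sliced to the queried (sub)grid."""

    def __init__(self, mask: BinaryMask):
        self.mask = mask

    def __call__(self, volume: CTVolume) -> BinaryMask:
        m = self.mask
        if volume.shape == m.shape and volume.same_geometry(m):
            return m
        off = []
        for ax in range(3):
            o = (volume.origin[ax] - m.origin[ax]) / m.spacing_mm[ax]
            oi = int(round(o))
            if abs(o - oi) > 1e-6 or oi < 0 or oi + volume.shape[ax] > m.shape[ax]:
                raise GeometryError("queried grid is not an aligned subgrid of the oracle mask")
            off.append(oi)
        sl = tuple(slice(o, o + s) for o, s in zip(off, volume.shape))
        return BinaryMask(m.values[sl], volume.spacing_mm, volume.origin)
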