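"""Sliding-window inference over whole volumes."""

from __future__ import annotations

import numpy as np

from ..core import BinaryMask, CTVolume
from .loss import sigmoid
from .model import ResidualUNet3D

__all__ = ["predict_probabilities", "predict_mask"]


def _window_starts(size: int, patch: int, stride: int) -> list[int]:
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch, stride))
    starts.append(size - patch)
    return starts


def predict_probabilities(model: ResidualUNet3D, volume: CTVolume) -> np.ndarray:
    """Per-voxel foreground probability by overlapping sliding windows.

    Windows advance by half a patch per axis; overlapping predictions are
    averaged.  Volumes smaller than the patch are zero-padded symmetrically
    and cropped back.  Deterministic for a fixed model.
    """
    cfg = model.config
    patch = cfg.patch_shape
    v = cfg.normalize(volume.values)
    orig_shape = v.shape
    pads = []
    for ax in range(3):
        short = max(0, patch[ax] - v.shape[ax])
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads):
        v = np.pad(v, pads)

    acc = np.zeros(v.shape, dtype=np.float64)
    weight = np.zeros(v.shape, dtype=np.float64)
    starts = [_window_starts(v.shape[ax], patch[ax], max(1, patch[ax] // 2))
              for ax in range(3)]
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = (slice(sx, sx + patch[0]), slice(sy, sy + patch[1]),
                      slice(sz, sz + patch[2]))
                logits = model.forward(v[sl][None, None])
                acc[sl] += sigmoid(logits)[0, 0]
                weight[sl] += 1.0
    probs = acc / weight
    crop = tuple(slice(p[0], p[0] + s) for p, s in zip(pads, orig_shape))
    return probs[crop].astype(np.float32)


def predict_mask(model: ResidualUNet3D, volume: CTVolume,
                 threshold: float = 0.5) -> BinaryMask:
    """Binarized sliding-window prediction sharing the volume's geometry."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    probs = predict_probabilities(model, volume)
    return BinaryMask(probs >= threshold, volume.spacing_mm, volume.origin)
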