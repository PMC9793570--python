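"""Combined Dice + cross-entropy segmentation loss.

The training objective is the weighted sum of a soft Dice loss and the mean
binary cross-entropy:

    L = w_d * (1 - (2 sum(p g) + s) / (sum(p) + sum(g) + s)) + w_c * BCE(p, g)

with a small additive smoothing constant s stabilizing empty masks.  The
gradient is taken with respect to the pre-sigmoid logits, for which both
terms have simple closed forms.
"""

from __future__ import annotations

import numpy as np

from ..core import BinaryMask

__all__ = ["combined_loss", "combined_loss_grad", "sigmoid", "soft_dice_loss",
           "cross_entropy_loss", "DEFAULT_SMOOTH"]

DEFAULT_SMOOTH = 1e-5
_EPS = 1e-7


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _as_array(reference) -> np.ndarray:
    if isinstance(reference, BinaryMask):
        return reference.values.astype(np.float32)
    return (np.asarray(reference) > 0.5).astype(np.float32)


def soft_dice_loss(p: np.ndarray, g: np.ndarray, smooth: float = DEFAULT_SMOOTH) -> float:
    num = 2.0 * float((p * g).sum()) + smooth
    den = float(p.sum()) + float(g.sum()) + smooth
    if den == 0:
        return 0.0
    return 1.0 - num / den


def cross_entropy_loss(p: np.ndarray, g: np.ndarray) -> float:
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())


def combined_loss(predicted_probabilities, reference, dice_weight: float = 1.0,
                  ce_weight: float = 1.0, smooth: float = DEFAULT_SMOOTH) -> float:
    """Weighted Dice + cross-entropy loss of per-voxel probabilities.

    Zero iff the prediction exactly equals the reference (with positive
    weights, up to the smoothing term).  Probabilities must lie in [0, 1]
    and match the reference shape.
    """
    p = np.asarray(predicted_probabilities, dtype=np.float64)
    g = _as_array(reference).astype(np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs reference {g.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if dice_weight < 0 or ce_weight < 0 or dice_weight + ce_weight <= 0:
        raise ValueError("weights must be >= 0 with a positive sum")
    loss = 0.0
    if dice_weight > 0:
        loss += dice_weight * soft_dice_loss(p, g, smooth)
    if ce_weight > 0:
        loss += ce_weight * cross_entropy_loss(p, g)
    return float(loss)


def combined_loss_grad(logits: np.ndarray, g: np.ndarray, dice_weight: float,
                       ce_weight: float, smooth: float = DEFAULT_SMOOTH
                       ) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the logits."""
    p = sigmoid(logits).astype(np.float64)
    g = g.astype(np.float64)
    n = p.size
    num = 2.0 * (p * g).sum() + smooth
    den = p.sum() + g.sum() + smooth
    loss = dice_weight * (1.0 - num / den) + ce_weight * cross_entropy_loss(p, g)
    # d(dice)/dp_i = -(2 g_i den - num) / den^2 ; chain through dp/dz = p(1-p)
    ddice_dp = -(2.0 * g * den - num) / (den * den)
    dz = ce_weight * (p - g) / n + dice_weight * ddice_dp * p * (1.0 - p)
    return float(loss), dz.astype(np.float32)
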