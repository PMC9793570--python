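"""Training loop with deep supervision, Adam, and patient-wise k-folds.

Patches are sampled from the training volumes with a foreground bias (half
of all patches are centered on a random foreground voxel), which keeps
small lesions represented in the batch stream.  Deep-supervision targets
are nearest-neighbour downsamplings of the reference mask; the auxiliary
losses are weighted by halving weights renormalized to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import BinaryMask, CTVolume, require_same_geometry
from .loss import combined_loss_grad
from .model import ResidualUNet3D

__all__ = ["TrainConfig", "FoldAssignment", "train", "make_folds", "AdamOptimizer"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-3
    epochs: int = 10
    batch_size: int = 2
    steps_per_epoch: int = 10
    dice_weight: float = 1.0
    ce_weight: float = 1.0
    fg_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dice_weight < 0 or self.ce_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if self.dice_weight + self.ce_weight <= 0:
            raise ValueError("at least one loss weight must be positive")
        if self.epochs < 0 or self.batch_size < 1 or self.steps_per_epoch < 1:
            raise ValueError("invalid epochs/batch_size/steps_per_epoch")


class AdamOptimizer:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass(frozen=True)
class FoldAssignment:
    """Patient-wise fold assignment: every case in exactly one fold."""

    assignment: dict[str, int]
    k: int

    def fold_of(self, case_id: str) -> int:
        return self.assignment[case_id]

    def fold_members(self, fold: int) -> list[str]:
        return [c for c, f in self.assignment.items() if f == fold]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes


def make_folds(case_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Balanced, seed-deterministic patient-wise partition into k folds.

    Fold sizes differ by at most one; the split is per patient, never per
    slice or per volume, so no case leaks across folds.
    """
    ids = list(case_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k = {k} exceeds the number of cases ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[int(i)]: int(pos % k) for pos, i in enumerate(order)}
    return FoldAssignment(assignment, k)


def _sample_patch(rng, vol: np.ndarray, mask: np.ndarray, fg_idx, patch, fg_bias):
    shape = vol.shape
    start = []
    if fg_idx is not None and len(fg_idx[0]) > 0 and rng.random() < fg_bias:
        j = rng.integers(len(fg_idx[0]))
        center = [int(ax[j]) for ax in fg_idx]
        for ax in range(3):
            s = int(np.clip(center[ax] - patch[ax] // 2, 0, shape[ax] - patch[ax]))
            start.append(s)
    else:
        for ax in range(3):
            start.append(int(rng.integers(0, shape[ax] - patch[ax] + 1)))
    sl = tuple(slice(s, s + p) for s, p in zip(start, patch))
    return vol[sl], mask[sl]


def _pad_to_patch(arr: np.ndarray, patch) -> np.ndarray:
    pads = [(0, max(0, p - s)) for s, p in zip(arr.shape, patch)]
    if any(p[1] for p in pads):
        arr = np.pad(arr, pads)
    return arr


def train(model: ResidualUNet3D, cases, tcfg: TrainConfig):
    """Train in place on (CTVolume, BinaryMask) pairs; returns (model, history).

    ``history`` is a list of per-epoch mean losses.  Zero epochs return the
    model unchanged with an empty history.  Fixed seeds make runs
    reproducible on one device.
    """
    if not cases:
        raise ValueError("training requires at least one case")
    for vol, mask in cases:
        require_same_geometry(vol, mask, "training volume and mask")
    if tcfg.epochs == 0:
        return model, []

    cfg = model.config
    patch = cfg.patch_shape
    prepared = []
    for vol, mask in cases:
        v = _pad_to_patch(cfg.normalize(vol.values), patch)
        m = _pad_to_patch(mask.values.astype(np.float32), patch)
        fg = np.nonzero(m > 0.5)
        prepared.append((v, m, fg if len(fg[0]) else None))

    n_heads = 1 + len(model.ds_heads)
    w = np.array([2.0**-i for i in range(n_heads)])
    head_w = w / w.sum()

    rng = np.random.default_rng(tcfg.seed)
    opt = AdamOptimizer(model.params(), tcfg.learning_rate)
    history = []
    for _epoch in range(tcfg.epochs):
        epoch_losses = []
        for _step in range(tcfg.steps_per_epoch):
            xs, ys = [], []
            for _ in range(tcfg.batch_size):
                ci = int(rng.integers(len(prepared)))
                v, m, fg = prepared[ci]
                xp, yp = _sample_patch(rng, v, m, fg, patch, tcfg.fg_bias)
                xs.append(xp)
                ys.append(yp)
            x = np.stack(xs)[:, None]
            y = np.stack(ys)[:, None]
            logits = model.forward(x, train=True)
            model.zero_grad()
            total = 0.0
            dl = []
            for i, lg in enumerate(logits):
                target = y[:, :, :: 2**i, :: 2**i, :: 2**i]
                loss_i, dz = combined_loss_grad(
                    lg, target, tcfg.dice_weight, tcfg.ce_weight
                )
                total += head_w[i] * loss_i
                dl.append(head_w[i] * dz)
            model.backward(dl)
            opt.step()
            epoch_losses.append(total)
        history.append(float(np.mean(epoch_losses)))
    return model, history
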