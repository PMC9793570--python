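"""Residual 3D encoder-decoder segmentation network ("dynamic U-Net" style).

Architecture: a U-Net whose encoder and decoder use residual blocks
(convolution -> instance norm -> leaky ReLU), two blocks per resolution
step; downsampling by strided convolution, upsampling by transposed
convolution; feature maps double on each downsampling and halve on each
upsampling.  Skip connections are channel concatenations.  Auxiliary
1x1-convolution heads on the coarser decoder levels provide deep
supervision during training.

The reference configuration from the literature uses 32 initial features at
GPU scale; the default here is desk-scale (3 levels, 8 features, 32^3
patches) so the full mechanism trains on a CPU, with the larger setting
available through the same config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import Conv3d, ConvTranspose3d, InstanceNorm3d, LeakyReLU

__all__ = ["DynUNetConfig", "ResidualUNet3D", "build_model",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class DynUNetConfig:
    n_levels: int = 3
    initial_features: int = 8
    res_blocks_per_level: int = 2
    leaky_slope: float = 0.01
    deep_supervision_heads: int = 2
    patch_shape: tuple[int, int, int] = (32, 32, 32)
    intensity_window: tuple[float, float] | None = (-50.0, 250.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_features < 1 or self.n_levels < 2:
            raise ValueError("need initial_features >= 1 and n_levels >= 2")
        if self.res_blocks_per_level < 1:
            raise ValueError("res_blocks_per_level must be >= 1")
        if self.deep_supervision_heads < 0:
            raise ValueError("deep_supervision_heads must be >= 0")
        if self.deep_supervision_heads > self.n_levels - 1:
            raise ValueError("deep_supervision_heads must be <= n_levels - 1")
        div = 2 ** (self.n_levels - 1)
        if any(p % div or p < div for p in self.patch_shape):
            raise ValueError(
                f"patch shape {self.patch_shape} must be divisible by "
                f"2^(n_levels-1) = {div}"
            )

    @property
    def feature_counts(self) -> list[int]:
        """Per-level encoder feature counts (doubling rule)."""
        return [self.initial_features * 2**l for l in range(self.n_levels)]

    def normalize(self, values: np.ndarray) -> np.ndarray:
        """Clip to the intensity window and min-max scale to [0, 1]."""
        v = np.asarray(values, dtype=np.float32)
        if self.intensity_window is None:
            lo, hi = float(v.min()), float(v.max())
            if hi == lo:
                return np.zeros_like(v)
        else:
            lo, hi = self.intensity_window
        return np.clip((v - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


class _ResBlock:
    """conv-IN-lrelu -> conv-IN, added to a (projected) skip, then lrelu."""

    def __init__(self, cin, cout, stride, slope, rng, name):
        self.conv1 = Conv3d(cin, cout, 3, stride, rng=rng, name=f"{name}.conv1")
        self.in1 = InstanceNorm3d(cout, name=f"{name}.in1")
        self.act1 = LeakyReLU(slope)
        self.conv2 = Conv3d(cout, cout, 3, 1, rng=rng, name=f"{name}.conv2")
        self.in2 = InstanceNorm3d(cout, name=f"{name}.in2")
        self.act_out = LeakyReLU(slope)
        if cin != cout or stride != 1:
            self.proj = Conv3d(cin, cout, 1, stride, pad=0, rng=rng, name=f"{name}.proj")
            self.proj_in = InstanceNorm3d(cout, name=f"{name}.proj_in")
        else:
            self.proj = None
            self.proj_in = None

    def params(self):
        ps = self.conv1.params() + self.in1.params() + self.conv2.params() + self.in2.params()
        if self.proj is not None:
            ps += self.proj.params() + self.proj_in.params()
        return ps

    def forward(self, x):
        h = self.act1.forward(self.in1.forward(self.conv1.forward(x)))
        h = self.in2.forward(self.conv2.forward(h))
        skip = x if self.proj is None else self.proj_in.forward(self.proj.forward(x))
        return self.act_out.forward(h + skip)

    def backward(self, dout):
        d = self.act_out.backward(dout)
        dskip = d
        dh = self.in2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.act1.backward(dh)
        dh = self.in1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.proj is not None:
            dskip = self.proj.backward(self.proj_in.backward(dskip))
        return dx + dskip


class _DecoderStage:
    def __init__(self, c_coarse, c_fine, n_blocks, slope, rng, name):
        self.up = ConvTranspose3d(c_coarse, c_fine, rng=rng, name=f"{name}.up")
        blocks = [_ResBlock(2 * c_fine, c_fine, 1, slope, rng, f"{name}.block0")]
        for i in range(1, n_blocks):
            blocks.append(_ResBlock(c_fine, c_fine, 1, slope, rng, f"{name}.block{i}"))
        self.blocks = blocks

    def params(self):
        ps = self.up.params()
        for b in self.blocks:
            ps += b.params()
        return ps

    def forward(self, x_coarse, skip):
        up = self.up.forward(x_coarse)
        self._split = up.shape[1]
        h = np.concatenate([up, skip], axis=1)
        for b in self.blocks:
            h = b.forward(h)
        return h

    def backward(self, dout):
        d = dout
        for b in reversed(self.blocks):
            d = b.backward(d)
        dup, dskip = d[:, : self._split], d[:, self._split:]
        dx = self.up.backward(np.ascontiguousarray(dup))
        return dx, np.ascontiguousarray(dskip)


class ResidualUNet3D:
    """The segmentation model: maps a patch to per-voxel foreground logits.

    ``forward(x, train=True)`` returns a list of logit grids — the full-
    resolution output first, then one per deep-supervision head at halved
    resolutions.  ``forward(x)`` returns only the full-resolution logits.
    """

    def __init__(self, config: DynUNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        feats = config.feature_counts
        slope = config.leaky_slope
        nb = config.res_blocks_per_level

        self.enc_levels = []
        cin = 1
        for l, f in enumerate(feats):
            stride = 1 if l == 0 else 2
            blocks = [_ResBlock(cin, f, stride, slope, rng, f"enc{l}.block0")]
            for i in range(1, nb):
                blocks.append(_ResBlock(f, f, 1, slope, rng, f"enc{l}.block{i}"))
            self.enc_levels.append(blocks)
            cin = f

        self.dec_stages = [
            _DecoderStage(feats[l], feats[l - 1], nb, slope, rng, f"dec{l}")
            for l in range(config.n_levels - 1, 0, -1)
        ]
        self.head = Conv3d(feats[0], 1, 1, 1, pad=0, bias=True, rng=rng, name="head")
        # deep-supervision heads on progressively coarser decoder outputs
        self.ds_heads = [
            Conv3d(feats[i + 1], 1, 1, 1, pad=0, bias=True, rng=rng, name=f"ds{i}")
            for i in range(config.deep_supervision_heads)
        ]

    def params(self):
        ps = []
        for blocks in self.enc_levels:
            for b in blocks:
                ps += b.params()
        for s in self.dec_stages:
            ps += s.params()
        ps += self.head.params()
        for h in self.ds_heads:
            ps += h.params()
        return ps

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False):
        x = np.asarray(x, dtype=np.float32)
        skips = []
        h = x
        for blocks in self.enc_levels:
            for b in blocks:
                h = b.forward(h)
            skips.append(h)
        dec_outs = [h]  # coarsest first
        for stage, skip in zip(self.dec_stages, reversed(skips[:-1])):
            h = stage.forward(h, skip)
            dec_outs.append(h)
        logits = self.head.forward(h)
        if not train:
            return logits
        outs = [logits]
        # decoder output at resolution level i+1 feeds deep-supervision head i
        for i, ds in enumerate(self.ds_heads):
            outs.append(ds.forward(dec_outs[-(i + 2)]))
        return outs

    def backward(self, dlogits: list[np.ndarray]):
        """Backpropagate the gradients of every head's logits.

        ``dlogits`` matches the output of ``forward(train=True)``: the
        full-resolution head gradient first, then the deep-supervision
        heads coarse-ward.
        """
        S = len(self.dec_stages)
        # gradient w.r.t. dec_outs[j], j = 0 (bottleneck) .. S (finest)
        gout: list[np.ndarray | None] = [None] * (S + 1)
        gout[S] = self.head.backward(dlogits[0])
        for i, ds in enumerate(self.ds_heads):
            if i + 1 < len(dlogits):
                j = S - 1 - i  # dec_outs index consumed by ds head i
                g = ds.backward(dlogits[i + 1])
                gout[j] = g if gout[j] is None else gout[j] + g
        dskips = []  # grad of encoder skips, level 0 first
        d = gout[S]
        for idx in range(S - 1, -1, -1):
            dx, dskip = self.dec_stages[idx].backward(d)
            dskips.append(dskip)
            if gout[idx] is not None:
                dx = dx + gout[idx]
            d = dx
        # encoder backward; skips[l] (l < L-1) feeds decoder stage S-1-l,
        # whose skip gradient was appended at position l above
        d_enc = d
        for l in range(len(self.enc_levels) - 1, -1, -1):
            if l < len(self.enc_levels) - 1:
                d_enc = d_enc + dskips[l]
            for b in reversed(self.enc_levels[l]):
                d_enc = b.backward(d_enc)
        return d_enc


def build_model(config: DynUNetConfig) -> ResidualUNet3D:
    """Build a seed-deterministic model from its configuration."""
    return ResidualUNet3D(config)


def save_checkpoint(model: ResidualUNet3D, path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    cfg = asdict(model.config)
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> ResidualUNet3D:
    data = np.load(path, allow_pickle=False)
    cfg = json.loads(str(data["__config__"]))
    for key in ("patch_shape", "intensity_window"):
        if cfg.get(key) is not None:
            cfg[key] = tuple(cfg[key])
    model = build_model(DynUNetConfig(**cfg))
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    return model
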