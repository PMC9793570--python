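"""3D network layers with explicit forward/backward passes.

All layers operate on float32 arrays shaped (batch, channels, D, H, W).
Convolutions are evaluated as a sum over kernel offsets of channel-mixing
GEMMs on shifted views of the (padded) input; the input gradient scatters
back through the same shifted views, so strided convolutions need no extra
machinery.  Each layer caches what its backward pass needs on forward;
backward returns the input gradient and accumulates parameter gradients
in-place.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv3d", "ConvTranspose3d", "InstanceNorm3d", "LeakyReLU"]


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv3d:
    """3D convolution (optionally strided), He-initialized, optional bias.

    Evaluated as a sum over the k^3 kernel offsets of small channel-mixing
    GEMMs on shifted views, which keeps memory traffic proportional to the
    input rather than to an unfolded patch matrix.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = False,
                 rng: np.random.Generator | None = None, name: str = ""):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k**3))
        self.w = Param(rng.normal(0.0, scale, (cout, cin, k, k, k)), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b") if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _out_shape(self, x_shape):
        k, s, p = self.k, self.stride, self.pad
        return tuple((n + 2 * p - k) // s + 1 for n in x_shape[2:])

    def _shift(self, xp, i, j, l, out_sp):
        s = self.stride
        Do, Ho, Wo = out_sp
        return xp[:, :, i:i + (Do - 1) * s + 1:s,
                  j:j + (Ho - 1) * s + 1:s,
                  l:l + (Wo - 1) * s + 1:s]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.pad
        B, cin = x.shape[:2]
        cout = self.w.value.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3) if p else x
        out_sp = self._out_shape(x.shape)
        n = int(np.prod(out_sp))
        out = np.zeros((B, cout, n), dtype=np.float32)
        wv = self.w.value
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = np.ascontiguousarray(
                        self._shift(xp, i, j, l, out_sp)).reshape(B, cin, n)
                    out += wv[:, :, i, j, l] @ xs
        out = out.reshape(B, cout, *out_sp)
        if self.b is not None:
            out += self.b.value[None, :, None, None, None]
        self._cache = (xp, x.shape, out_sp)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape, out_sp = self._cache
        self._cache = None
        k, s, p = self.k, self.stride, self.pad
        B, cin = x_shape[:2]
        cout = self.w.value.shape[0]
        n = int(np.prod(out_sp))
        dm = dout.reshape(B, cout, n)
        dxp = np.zeros_like(xp)
        wv = self.w.value
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = np.ascontiguousarray(
                        self._shift(xp, i, j, l, out_sp)).reshape(B, cin, n)
                    # (B,Cout,n) x (B,Cin,n) summed over batch and voxels
                    self.w.grad[:, :, i, j, l] += np.einsum(
                        "bon,bcn->oc", dm, xs, optimize=True)
                    dxs = (wv[:, :, i, j, l].T @ dm).reshape(B, cin, *out_sp)
                    self._shift(dxp, i, j, l, out_sp)[...] += dxs
        if self.b is not None:
            self.b.grad += dm.sum(axis=(0, 2))
        if p:
            dxp = dxp[:, :, p:p + x_shape[2], p:p + x_shape[3], p:p + x_shape[4]]
        return np.ascontiguousarray(dxp)


class ConvTranspose3d:
    """Transposed convolution with kernel = stride = 2 (exact 2x upsampling).

    Each input voxel maps to a disjoint 2x2x2 output block, so forward and
    backward are plain einsums with no overlap bookkeeping.
    """

    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None, name: str = ""):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * 8))
        self.w = Param(rng.normal(0.0, scale, (cin, cout, 2, 2, 2)), f"{name}.w")
        self._cache = None

    def params(self):
        return [self.w]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        out = np.einsum("bcdhw,coijl->bodihjwl", x, self.w.value, optimize=True)
        self._cache = x
        cout = self.w.value.shape[1]
        return np.ascontiguousarray(out).reshape(B, cout, 2 * D, 2 * H, 2 * W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        B, C, D, H, W = x.shape
        cout = self.w.value.shape[1]
        dr = dout.reshape(B, cout, D, 2, H, 2, W, 2)
        self.w.grad += np.einsum("bcdhw,bodihjwl->coijl", x, dr, optimize=True)
        dx = np.einsum("bodihjwl,coijl->bcdhw", dr, self.w.value, optimize=True)
        return np.ascontiguousarray(dx.astype(np.float32))


class InstanceNorm3d:
    """Instance normalization with learnable per-channel scale and shift.

    Statistics are computed per (sample, channel) over the spatial axes, so
    inference behaves identically to training (no running averages).
    """

    def __init__(self, channels: int, eps: float = 1e-5, name: str = ""):
        self.eps = eps
        self.g = Param(np.ones(channels), f"{name}.g")
        self.b = Param(np.zeros(channels), f"{name}.b")
        self._cache = None

    def params(self):
        return [self.g, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat.astype(np.float32), inv.astype(np.float32))
        return (self.g.value[None, :, None, None, None] * xhat
                + self.b.value[None, :, None, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        axes = (2, 3, 4)
        n = float(np.prod(xhat.shape[2:]))
        self.g.grad += (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        dxhat = dout * self.g.value[None, :, None, None, None]
        # standard normalized-input backward, per (b, c)
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) * inv
        return dx.astype(np.float32)


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return np.where(mask, dout, self.slope * dout).astype(np.float32)
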