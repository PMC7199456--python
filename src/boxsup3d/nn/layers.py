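"""Differentiable 3D layers on NumPy arrays.

Stride-1 'same' convolutions are computed as one batched GEMM applying all
k^3 kernel taps to every voxel of the zero-padded volume, followed by
shift-and-add accumulation of the tap planes — algebraically identical to
im2col but without its k^3-fold gather, which dominates runtime at patch
scale.  The input gradient is the same operation with spatially flipped,
channel-transposed kernels.  Every layer caches what its backward needs on
``forward`` and frees it afterwards; gradients accumulate into
``.dW``/``.db``.

All tensors are (N, C, D, H, W).
"""

from __future__ import annotations

import itertools

import numpy as np


def _tap_offsets(k: int):
    return list(itertools.product(range(k), range(k), range(k)))


def _flatten_padded(x: np.ndarray, pad: int):
    """Zero-pad spatially and flatten to (C, N*Pp) with per-sample blocks."""
    n, c = x.shape[:2]
    xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    pshape = xp.shape[2:]
    flat = np.ascontiguousarray(xp.transpose(1, 0, 2, 3, 4)).reshape(c, -1)
    return flat, pshape


def _conv_same(x: np.ndarray, weights: np.ndarray, k: int, pad: int) -> np.ndarray:
    """sum_t W_t @ xpad(p + t): stride-1 'same' correlation.

    Works on the flattened padded volume: each kernel tap becomes one
    (F, C) GEMM followed by a flat-offset shifted accumulation.  Shifts
    that cross sample or row boundaries only pollute padded positions,
    which the final crop discards.  ``weights`` is (F, C, k, k, k);
    returns (N, F, D, H, W).
    """
    n, c, d, h, w = x.shape
    f = weights.shape[0]
    flat, (dp, hp, wp) = _flatten_padded(x, pad)
    m = flat.shape[1]
    acc = np.zeros((f, m), dtype=x.dtype)
    for i, j, l in _tap_offsets(k):
        off = (i - pad) * hp * wp + (j - pad) * wp + (l - pad)
        y = weights[:, :, i, j, l] @ flat
        if off >= 0:
            acc[:, : m - off] += y[:, off:]
        else:
            acc[:, -off:] += y[:, : m + off]
    out = acc.reshape(f, n, dp, hp, wp)[
        :, :, pad : pad + d, pad : pad + h, pad : pad + w
    ]
    return np.ascontiguousarray(out.transpose(1, 0, 2, 3, 4))


class Conv3d:
    """k^3 stride-1 convolution with 'same' zero padding and bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = c_in * k**3
        self.W = (rng.standard_normal((c_out, c_in, k, k, k)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k, self.pad = k, k // 2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = _conv_same(x, self.W, self.k, self.pad)
        out += self.b[None, :, None, None, None]
        if train:
            self._cache = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        k, pad = self.k, self.pad
        xflat, (dp, hp, wp) = _flatten_padded(x, pad)
        dflat, _ = _flatten_padded(dout, pad)
        m = xflat.shape[1]
        # dW_t = sum over voxels of dout(p) (x) xpad(p + t); the embedded
        # dout is zero on every padded position, so flat-offset overruns
        # across rows or samples multiply zeros
        for i, j, l in _tap_offsets(k):
            off = (i - pad) * hp * wp + (j - pad) * wp + (l - pad)
            if off >= 0:
                g = dflat[:, : m - off] @ xflat[:, off:].T
            else:
                g = dflat[:, -off:] @ xflat[:, : m + off].T
            self.dW[:, :, i, j, l] += g.astype(self.dW.dtype)
        self.db += dout.sum(axis=(0, 2, 3, 4)).astype(self.db.dtype)
        # dx: correlate dout with flipped kernels, in/out channels swapped
        w_flip = np.ascontiguousarray(
            self.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        return _conv_same(dout, w_flip, k, pad)


class InstanceNorm:
    """Per-sample, per-channel standardization over the spatial axes (no affine)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps
        self._cache = None

    n_params = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = (x - mu) * inv
        if train:
            self._cache = (y, inv)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        y, inv = self._cache
        self._cache = None
        axes = (2, 3, 4)
        m1 = dout.mean(axis=axes, keepdims=True)
        m2 = (dout * y).mean(axis=axes, keepdims=True)
        return inv * (dout - m1 - y * m2)


class ReLU:
    n_params = 0

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dout * mask


class MaxPool2:
    """2x2x2 max pooling; ties share the gradient equally."""

    n_params = 0

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        blocks = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = blocks.max(axis=(3, 5, 7))
        if train:
            self._cache = (blocks, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        blocks, out = self._cache
        self._cache = None
        mask = blocks == out[:, :, :, None, :, None, :, None]
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        g = mask * (dout[:, :, :, None, :, None, :, None] / counts)
        n, c = g.shape[:2]
        d = g.shape[2] * 2
        h = g.shape[4] * 2
        w = g.shape[6] * 2
        return g.reshape(n, c, d, h, w)


class Upsample2:
    """Nearest-neighbor 2x upsampling; backward sums each 2x2x2 block."""

    n_params = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = dout.shape
        return dout.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))
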