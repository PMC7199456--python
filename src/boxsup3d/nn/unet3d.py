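"""Compact 3D U-Net producing per-voxel logits.

Encoder/decoder with skip connections; each stage is two 3x3x3 convolutions
with instance normalization and ReLU, stages are joined by 2x max pooling
and nearest-neighbor upsampling, and a final 1x1x1 convolution maps to one
logit channel at input resolution.  Relative to the reference 3D U-Net the
deepest pooling stage is dropped (depth defaults shallow), trading
receptive field for preserved boundary detail at patch scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .layers import Conv3d, InstanceNorm, MaxPool2, ReLU, Upsample2


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture knobs; ``patch_size`` must be divisible by 2**depth."""

    in_channels: int = 8
    base_filters: int = 8
    depth: int = 2
    patch_size: int = 16
    dtype: str = "float32"

    def __post_init__(self):
        if self.patch_size % (2**self.depth) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^depth={2**self.depth}"
            )
        if self.depth < 1 or self.base_filters < 1 or self.in_channels < 1:
            raise ValueError("depth, base_filters and in_channels must be >= 1")


class _ConvBlock:
    """Conv-IN-ReLU twice; the workhorse stage of the network."""

    def __init__(self, c_in, c_out, rng, dtype):
        self.layers = [
            Conv3d(c_in, c_out, 3, rng, dtype),
            InstanceNorm(),
            ReLU(),
            Conv3d(c_out, c_out, 3, rng, dtype),
            InstanceNorm(),
            ReLU(),
        ]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def convs(self):
        return [l for l in self.layers if isinstance(l, Conv3d)]


class UNet3D:
    """Seeded network instance; parameters live in the layer objects."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        dtype = np.dtype(cfg.dtype).type
        f = cfg.base_filters
        self.enc = []
        c_in = cfg.in_channels
        for i in range(cfg.depth):
            self.enc.append(_ConvBlock(c_in, f * 2**i, rng, dtype))
            c_in = f * 2**i
        self.pools = [MaxPool2() for _ in range(cfg.depth)]
        self.bottleneck = _ConvBlock(c_in, f * 2**cfg.depth, rng, dtype)
        self.ups = [Upsample2() for _ in range(cfg.depth)]
        self.dec = []
        for i in reversed(range(cfg.depth)):
            self.dec.append(_ConvBlock(f * 2 ** (i + 1) + f * 2**i, f * 2**i, rng, dtype))
        self.head = Conv3d(f, 1, 1, rng, dtype)
        self._skip_channels = None

    # -- parameter plumbing -------------------------------------------------
    def _blocks(self):
        return self.enc + [self.bottleneck] + self.dec

    def conv_layers(self) -> list[Conv3d]:
        convs = []
        for b in self._blocks():
            convs.extend(b.convs())
        convs.append(self.head)
        return convs

    def parameters(self) -> list[np.ndarray]:
        out = []
        for c in self.conv_layers():
            out.extend([c.W, c.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for c in self.conv_layers():
            out.extend([c.dW, c.db])
        return out

    def set_parameters(self, values) -> None:
        params = self.parameters()
        if len(values) != len(params):
            raise ValueError("parameter list length mismatch")
        for p, v in zip(params, values):
            p[...] = v

    def zero_grad(self) -> None:
        for c in self.conv_layers():
            c.dW[...] = 0
            c.db[...] = 0

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, in_channels, d, d, d) -> (N, 1, d, d, d) logits."""
        x = np.asarray(x)
        if x.ndim != 5 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (N, {self.cfg.in_channels}, d, d, d) input, got {x.shape}"
            )
        if any(s % (2**self.cfg.depth) for s in x.shape[2:]):
            raise ValueError(f"spatial sides of {x.shape[2:]} must divide 2^depth")
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        if train:
            self._skip_channels = [s.shape[1] for s in skips]
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = block.forward(np.concatenate([x, skip], axis=1), train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients; pair with ``forward(train=True)``."""
        d = self.head.backward(np.asarray(dlogits))
        # dec[j] consumed skips[depth-1-j]; walking dec in reverse therefore
        # yields skip gradients in forward skip order (enc0 first)
        dskips = []
        for up, block in zip(reversed(self.ups), reversed(self.dec)):
            d = block.backward(d)
            c_skip = self._skip_channels[len(dskips)]
            d, dskip = d[:, :-c_skip], d[:, -c_skip:]
            dskips.append(dskip)
            d = up.backward(d)
        d = self.bottleneck.backward(d)
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = block.backward(d + dskip)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write parameters (.npz) and a JSON sidecar with config and seed."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"config": asdict(self.cfg), "seed": self.seed}))

    @classmethod
    def load(cls, path: str | Path) -> "UNet3D":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        net = cls(NetworkConfig(**sidecar["config"]), seed=sidecar["seed"])
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            net.set_parameters([data[f"p{i}"] for i in range(len(data.files))])
        return net


def build_network(cfg: NetworkConfig, seed: int = 0) -> UNet3D:
    """Construct a seeded network (two builds with one seed are identical)."""
    return UNet3D(cfg, seed=seed)
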