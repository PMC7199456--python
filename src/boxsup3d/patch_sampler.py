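"""Patch extraction with box-derived labels and multiscale network input.

Training patches are drawn around random center voxels, 80% from inside the
box (region S1, every voxel labeled 1 = unlabeled/tumor candidate) and 20%
from outside (region S0, labeled 0 = known background).  The network input
stacks, per modality, the patch at native scale and a 2x-larger patch
resampled down to the same side, giving 2 * n_modalities channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .volume_io import BoxAnnotation, MultimodalVolume


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling geometry and budget.

    ``patch_size`` of 48 with ``n_candidates=40000``/``n_selected=200``
    matches full-scale training; the defaults here are the desk scale.
    """

    patch_size: int = 16
    scale_factor: int = 2
    n_candidates: int = 4000
    n_selected: int = 200
    fraction_s1: float = 0.8
    min_nonzero_fraction: float = 0.0  # optional brain-content filter, off by default
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fraction_s1 < 1.0:
            raise ValueError(f"fraction_s1 must lie strictly in (0, 1), got {self.fraction_s1}")
        if self.n_selected > self.n_candidates:
            raise ValueError("n_selected must not exceed n_candidates")
        if self.patch_size < 2 or self.scale_factor < 1:
            raise ValueError("invalid patch geometry")


@dataclass(frozen=True)
class PatchSample:
    """One training sample: multiscale features plus box-derived labels."""

    features: np.ndarray  # (2*C, d, d, d) float32
    label_volume: np.ndarray  # (d, d, d) uint8; 1 = inside box
    region_tag: str  # "S1" | "S0"
    center: tuple[int, int, int]
    patient_id: str

    def __post_init__(self):
        if self.region_tag not in ("S1", "S0"):
            raise ValueError(f"region_tag must be S1 or S0, got {self.region_tag}")
        if self.features.shape[1:] != self.label_volume.shape:
            raise ValueError("feature and label spatial shapes differ")
        if self.region_tag == "S0" and self.label_volume.any():
            raise ValueError("S0 patch must have an all-zero label volume")


def sample_centers(
    volume_shape, box: BoxAnnotation, cfg: SamplerConfig, valid_fn=None
) -> list[tuple[tuple[int, int, int], str]]:
    """Seeded stratified center sampling.

    Draws ``n_candidates`` uniform voxel locations, partitions them by
    region, and subsamples exactly ``round(n_selected * fraction_s1)``
    S1 centers and the remainder from S0 (uniform within each stratum).
    ``valid_fn(center) -> bool``, if given, rejects candidates before
    subsampling (e.g. the minimum-brain-content filter); quotas are
    preserved by drawing further candidates as needed.
    """
    box.check_bounds(volume_shape)
    rng = np.random.default_rng(cfg.seed)
    n_s1 = int(round(cfg.n_selected * cfg.fraction_s1))
    n_s0 = cfg.n_selected - n_s1

    cand = np.stack(
        [rng.integers(0, s, size=cfg.n_candidates) for s in volume_shape], axis=1
    )
    lo = np.array(box.low)
    hi = np.array(box.high)
    inside = np.all((cand >= lo) & (cand < hi), axis=1)
    s1_pool = cand[inside]
    s0_pool = cand[~inside]
    if valid_fn is not None:
        s1_pool = np.array([c for c in s1_pool if valid_fn(tuple(c))], dtype=int).reshape(-1, 3)
        s0_pool = np.array([c for c in s0_pool if valid_fn(tuple(c))], dtype=int).reshape(-1, 3)

    # uniform top-up: the box typically covers a tiny volume fraction, so
    # candidate draws alone may not yield enough S1 centers
    attempts = 0
    while len(s1_pool) < n_s1:
        extra = np.stack([rng.integers(l, h, size=n_s1) for l, h in zip(lo, hi)], axis=1)
        if valid_fn is not None:
            extra = np.array([c for c in extra if valid_fn(tuple(c))], dtype=int).reshape(-1, 3)
        s1_pool = np.concatenate([s1_pool, extra], axis=0)
        attempts += 1
        if attempts > 100:
            raise ValueError("cannot find enough valid S1 patch centers")
    attempts = 0
    while len(s0_pool) < n_s0 and valid_fn is not None and attempts <= 100:
        extra = np.stack([rng.integers(0, s, size=n_s0) for s in volume_shape], axis=1)
        keep = ~np.all((extra >= lo) & (extra < hi), axis=1)
        extra = np.array(
            [c for c in extra[keep] if valid_fn(tuple(c))], dtype=int
        ).reshape(-1, 3)
        s0_pool = np.concatenate([s0_pool, extra], axis=0)
        attempts += 1
    if len(s0_pool) < n_s0:
        raise ValueError(
            "region S0 too small to host the requested number of patch centers"
        )

    s1_idx = rng.choice(len(s1_pool), size=n_s1, replace=False)
    s0_idx = rng.choice(len(s0_pool), size=n_s0, replace=False)
    centers = [(tuple(int(v) for v in s1_pool[i]), "S1") for i in s1_idx]
    centers += [(tuple(int(v) for v in s0_pool[i]), "S0") for i in s0_idx]
    return centers


def _window_bounds(center, d, shape):
    """Half-open window of side d with floor-center convention."""
    half_lo = d // 2
    lows = [c - half_lo for c in center]
    highs = [l + d for l in lows]
    return lows, highs


def extract_patch(volume: np.ndarray, center, d: int) -> np.ndarray:
    """Cubic window of side ``d`` around ``center``, zero-padded out of bounds.

    ``volume`` is (C, X, Y, Z); the center voxel lands at index d//2.
    """
    shape = volume.shape[1:]
    if any(not 0 <= c < s for c, s in zip(center, shape)):
        raise ValueError(f"center {center} outside volume of shape {shape}")
    if any(d > 2 * s for s in shape):
        raise ValueError(f"patch side {d} too large for volume shape {shape}")
    lows, highs = _window_bounds(center, d, shape)
    out = np.zeros((volume.shape[0], d, d, d), dtype=volume.dtype)
    src = tuple(slice(max(l, 0), min(h, s)) for l, h, s in zip(lows, highs, shape))
    dst = tuple(
        slice(max(l, 0) - l, d - (h - min(h, s))) for l, h, s in zip(lows, highs, shape)
    )
    out[(slice(None),) + dst] = volume[(slice(None),) + src]
    return out


def label_patch(center, d: int, box: BoxAnnotation, volume_shape=None) -> np.ndarray:
    """Binary label window: voxel = 1 iff its absolute coordinate is in the box.

    Out-of-volume padding is 0, so a patch straddling a box face carries
    exactly the box-window intersection as positives.
    """
    lows, _ = _window_bounds(center, d, box.high)
    label = np.zeros((d, d, d), dtype=np.uint8)
    sl = []
    for ax in range(3):
        a = max(box.low[ax], lows[ax])
        b = min(box.high[ax], lows[ax] + d)
        if volume_shape is not None:
            a, b = max(a, 0), min(b, volume_shape[ax])
        if a >= b:
            return label
        sl.append(slice(a - lows[ax], b - lows[ax]))
    label[tuple(sl)] = 1
    return label


def build_multiscale_input(
    vol: MultimodalVolume, center, cfg: SamplerConfig
) -> np.ndarray:
    """(2C, d, d, d) input: native patch plus downsized ``scale_factor*d`` patch.

    The wide patch shares the same center and is resampled to side ``d``
    with trilinear (order-1 spline) interpolation, adding coarse context
    channels without growing the network's receptive field.
    """
    d = cfg.patch_size
    fine = extract_patch(vol.intensities, center, d)
    if cfg.scale_factor == 1:
        return np.concatenate([fine, fine], axis=0).astype(np.float32)
    wide = extract_patch(vol.intensities, center, cfg.scale_factor * d)
    coarse = np.empty_like(fine)
    for c in range(wide.shape[0]):
        coarse[c] = zoom(wide[c], 1.0 / cfg.scale_factor, order=1, grid_mode=True, mode="grid-constant")
    return np.concatenate([fine, coarse], axis=0).astype(np.float32)


def sample_patches(
    vol: MultimodalVolume, box: BoxAnnotation, cfg: SamplerConfig
) -> list[PatchSample]:
    """Full per-patient sampling: centers, multiscale features, box labels.

    With ``min_nonzero_fraction`` > 0, candidate centers whose patch has a
    smaller fraction of brain (any-channel-nonzero) voxels are rejected
    before the stratified subsampling, so the selected count and the
    S1/S0 proportions stay exact.
    """
    valid_fn = None
    if cfg.min_nonzero_fraction > 0:
        brain = np.any(vol.intensities != 0, axis=0)

        def valid_fn(center):
            window = extract_patch(brain[None], center, cfg.patch_size)
            return window.mean() >= cfg.min_nonzero_fraction

    centers = sample_centers(vol.shape, box, cfg, valid_fn=valid_fn)
    samples = []
    for center, tag in centers:
        feats = build_multiscale_input(vol, center, cfg)
        label = label_patch(center, cfg.patch_size, box, vol.shape)
        if tag == "S0":
            # center outside the box; any box overlap in the window is still
            # unlabeled territory, but an S0 patch is defined as all-positive
            label = np.zeros_like(label)
        samples.append(PatchSample(feats, label, tag, center, vol.patient_id))
    return samples
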