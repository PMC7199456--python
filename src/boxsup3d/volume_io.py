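"""Volume containers, NIfTI I/O, normalization, boxes and the class prior.

The central weak-supervision objects live here: ``BoxAnnotation`` splits a
volume into the unlabeled region S1 (inside the box, tumor plus background)
and the positively labeled region S0 (outside the box, background only), and
``ClassPrior`` carries the background fraction pi_p used by the PU risk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITY_ORDER = ("flair", "t2", "t1", "t1ce")


@dataclass(frozen=True)
class MultimodalVolume:
    """Channel-stacked 3D study: ``intensities`` is (C, X, Y, Z)."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_id: str = "unknown"

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        if arr.ndim != 4:
            raise ValueError(f"intensities must be (C, X, Y, Z), got shape {arr.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]


@dataclass(frozen=True)
class BoxAnnotation:
    """Axis-aligned half-open box ``[low, high)``; inside = S1 (unlabeled)."""

    low: tuple[int, int, int]
    high: tuple[int, int, int]

    def __post_init__(self):
        if len(self.low) != 3 or len(self.high) != 3:
            raise ValueError("box corners must be voxel triples")
        if any(l >= h for l, h in zip(self.low, self.high)):
            raise ValueError(f"need low < high per axis, got {self.low}..{self.high}")
        if any(l < 0 for l in self.low):
            raise ValueError("box extends below 0")

    def check_bounds(self, volume_shape) -> None:
        if any(h > s for h, s in zip(self.high, volume_shape)):
            raise ValueError(f"box {self.high} exceeds volume shape {tuple(volume_shape)}")

    @property
    def volume(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.low, self.high)]))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.low, self.high))

    def contains(self, point) -> bool:
        return all(l <= p < h for l, p, h in zip(self.low, point, self.high))

    def mask(self, volume_shape) -> np.ndarray:
        m = np.zeros(volume_shape, dtype=bool)
        m[self.slices()] = True
        return m

    def to_json(self, path: str | Path, patient_id: str = "unknown") -> None:
        Path(path).write_text(
            json.dumps({"low": list(self.low), "high": list(self.high), "patient_id": patient_id})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BoxAnnotation":
        d = json.loads(Path(path).read_text())
        return cls(low=tuple(d["low"]), high=tuple(d["high"]))


@dataclass(frozen=True)
class ClassPrior:
    """Fraction pi_p of voxels belonging to the positive (background) class."""

    pi_p: float

    def __post_init__(self):
        if not 0.0 < self.pi_p < 1.0:
            raise ValueError(f"pi_p must lie strictly inside (0, 1), got {self.pi_p}")


#: operating value used for training throughout, unless recomputed per cohort
DEFAULT_PI_P = 0.75


def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_volume(paths: dict[str, str | Path], patient_id: str = "unknown") -> MultimodalVolume:
    """Read one study from per-modality NIfTI files.

    ``paths`` maps modality name to file; channel order is fixed as
    FLAIR, T2, T1, T1ce.  All files must agree on shape and spacing.
    """
    missing = [m for m in MODALITY_ORDER if m not in paths]
    if missing:
        raise FileNotFoundError(f"missing modalities: {', '.join(missing)}")
    channels, spacings, shapes = [], [], []
    for name in MODALITY_ORDER:
        data, spacing = _load_nifti(paths[name])
        channels.append(data)
        spacings.append(spacing)
        shapes.append(data.shape)
    if len({s for s in shapes}) != 1:
        raise ValueError(f"modalities disagree on shape: {dict(zip(MODALITY_ORDER, shapes))}")
    if any(not np.allclose(s, spacings[0]) for s in spacings[1:]):
        raise ValueError(f"modalities disagree on spacing: {spacings}")
    return MultimodalVolume(np.stack(channels, axis=0), spacings[0], patient_id)


def write_volume(channel: np.ndarray, spacing, path: str | Path) -> None:
    """Write one channel as NIfTI with the given voxel spacing (mm)."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(channel, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    data, _ = _load_nifti(path)
    return data > 0.5


def normalize_volume(vol: MultimodalVolume) -> MultimodalVolume:
    """Per-channel z-score over brain voxels only.

    Brain voxels are those with value != 0; the surrounding exactly-zero
    background is excluded from the statistics and left at 0, so the box
    region and the brain interior keep comparable scales across studies.
    Uses the population standard deviation.
    """
    out = np.zeros_like(vol.intensities, dtype=np.float32)
    for c in range(vol.n_channels):
        ch = vol.intensities[c]
        brain = ch != 0
        if brain.sum() < 2:
            raise ValueError(f"channel {c}: fewer than 2 nonzero voxels")
        vals = ch[brain].astype(np.float64)
        sd = vals.std()  # population std
        if sd == 0:
            raise ValueError(f"channel {c}: constant brain region, zero std")
        out[c][brain] = ((vals - vals.mean()) / sd).astype(np.float32)
    return MultimodalVolume(out, vol.spacing, vol.patient_id)


def box_from_mask(mask: np.ndarray, margin: int = 0) -> BoxAnnotation:
    """Tight axis-aligned bounding box of all positive voxels.

    ``margin`` symmetrically pads each face (clipped to the volume); the
    default is a tight box.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot derive a box from an empty mask")
    low, high = [], []
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(proj)
        low.append(max(int(idx[0]) - margin, 0))
        high.append(min(int(idx[-1]) + 1 + margin, mask.shape[ax]))
    return BoxAnnotation(low=tuple(low), high=tuple(high))


def class_prior(box: BoxAnnotation, volume_shape) -> ClassPrior:
    """pi_p = n0 / (n0 + n1): voxels outside the box over all voxels."""
    box.check_bounds(volume_shape)
    n_total = int(np.prod(volume_shape))
    n1 = box.volume
    n0 = n_total - n1
    if n0 == 0:
        raise ValueError("box covers the whole volume; pi_p would be 0")
    return ClassPrior(pi_p=n0 / n_total)
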