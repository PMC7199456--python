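"""Synthetic multimodal phantoms with known tumor masks.

Each phantom mimics a preprocessed multimodal brain MRI study: four
co-registered channels (FLAIR, T2, T1, T1ce order), a roughly spherical
"brain" of nonzero intensity surrounded by exactly-zero background, and one
or more tumors built from unions of overlapping ellipsoids whose intensity
offset differs per channel.  Because the ground-truth mask is known by
construction, tight bounding boxes, class priors and segmentation metrics
can all be verified without any external dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .volume_io import MultimodalVolume, box_from_mask, write_volume, write_mask

#: default per-channel tumor intensity offsets, FLAIR/T2 hyperintense,
#: T1 mildly hypointense, T1ce moderately enhancing
DEFAULT_CONTRAST = (1.0, 0.8, -0.3, 0.5)

BRAIN_MEAN = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic study.

    Parameters
    ----------
    volume_shape : tuple of int
        Voxel grid, each axis >= 16.
    n_modalities : int
        Number of channels (4 emulates FLAIR/T2/T1/T1ce).
    brain_radius_fraction : float
        Brain sphere radius as a fraction of half the smallest axis.
    tumor_count : int
        Number of disjoint tumors (0 gives an empty mask).
    tumor_radii_range : (float, float)
        Per-axis semi-axis range of the tumor ellipsoids, voxels.
    tumor_contrast : tuple of float
        Additive intensity offset of tumor tissue per channel.
    n_ellipsoids : int
        Ellipsoids unioned per tumor (1..3); satellite centers are kept
        inside the primary ellipsoid so each tumor is 6-connected.
    noise_sd : float
        Standard deviation of the additive Gaussian noise, intensity units.
    seed : int
        Fully determines the phantom (bit-identical regeneration).
    """

    volume_shape: tuple[int, int, int] = (64, 64, 64)
    n_modalities: int = 4
    brain_radius_fraction: float = 0.8
    tumor_count: int = 1
    tumor_radii_range: tuple[float, float] = (6.0, 12.0)
    tumor_contrast: tuple[float, ...] = DEFAULT_CONTRAST
    n_ellipsoids: int = 2
    noise_sd: float = 0.2
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        shape = tuple(int(s) for s in self.volume_shape)
        if len(shape) != 3 or any(s < 16 for s in shape):
            raise ValueError(f"volume_shape must be 3 axes of >= 16 voxels, got {shape}")
        if not 0 < self.brain_radius_fraction <= 1:
            raise ValueError("brain_radius_fraction must lie in (0, 1]")
        if self.tumor_count < 0:
            raise ValueError("tumor_count must be >= 0")
        if len(self.tumor_contrast) != self.n_modalities:
            raise ValueError("tumor_contrast needs one offset per modality")
        if not 1 <= self.n_ellipsoids <= 3:
            raise ValueError("n_ellipsoids must be 1..3")
        lo, hi = self.tumor_radii_range
        if not 0 < lo <= hi:
            raise ValueError("tumor_radii_range must satisfy 0 < lo <= hi")
        if hi >= self._brain_radius():
            raise ValueError(
                f"max tumor radius {hi} must be strictly smaller than "
                f"brain radius {self._brain_radius():.1f}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def _brain_radius(self) -> float:
        return self.brain_radius_fraction * min(self.volume_shape) / 2.0


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    """Lattice points with sum((x-c)^2/r^2) <= 1."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _sample_tumor_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """One tumor: union of 1-3 overlapping ellipsoids, fully inside the brain."""
    shape = spec.volume_shape
    brain_c = np.array(shape) / 2.0
    brain_r = spec._brain_radius()
    lo, hi = spec.tumor_radii_range
    radii = rng.uniform(lo, hi, size=3)
    rmax = float(radii.max())
    # center such that every satellite (radius <= rmax, center inside the
    # primary ellipsoid) stays inside the brain sphere
    margin = brain_r - 2.0 * rmax - 1.0
    if margin <= 0:
        margin = max(brain_r - rmax - 1.0, 1.0)
    offset = rng.uniform(-1.0, 1.0, size=3)
    offset *= margin / max(np.linalg.norm(offset), 1e-9) * rng.uniform(0, 1) ** (1 / 3)
    center = brain_c + offset
    mask = _ellipsoid_mask(shape, center, radii)
    for _ in range(spec.n_ellipsoids - 1):
        sat_radii = rng.uniform(lo, hi, size=3) * 0.7
        u = rng.uniform(-0.8, 0.8, size=3)
        sat_center = center + u * radii  # inside the primary ellipsoid
        mask |= _ellipsoid_mask(shape, sat_center, sat_radii)
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[MultimodalVolume, np.ndarray]:
    """Generate one multimodal phantom and its ground-truth tumor mask.

    Returns
    -------
    volume : MultimodalVolume
        ``(n_modalities, *volume_shape)`` float32 intensities; exactly 0
        outside the brain sphere.
    mask : ndarray of bool
        Ground-truth tumor mask (union over tumors).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.volume_shape)
    brain = _ellipsoid_mask(shape, np.array(shape) / 2.0, [spec._brain_radius()] * 3)

    mask = np.zeros(shape, dtype=bool)
    for _ in range(spec.tumor_count):
        mask |= _sample_tumor_mask(spec, rng)
    mask &= brain  # guaranteed no-op by construction, kept as a hard invariant

    channels = np.zeros((spec.n_modalities,) + shape, dtype=np.float32)
    for c in range(spec.n_modalities):
        ch = np.full(shape, BRAIN_MEAN, dtype=np.float64)
        ch[mask] += spec.tumor_contrast[c]
        if spec.noise_sd > 0:
            ch += rng.normal(0.0, spec.noise_sd, size=shape)
        ch[~brain] = 0.0
        channels[c] = ch.astype(np.float32)
    vol = MultimodalVolume(
        intensities=channels,
        spacing=spec.spacing,
        patient_id=f"phantom-{spec.seed:08d}",
    )
    return vol, mask


def generate_cohort(
    n_patients: int, spec_template: PhantomSpec, seed: int
) -> list[tuple[MultimodalVolume, np.ndarray]]:
    """Seeded cohort with per-patient variation of tumor size/position/contrast.

    Each patient gets an independent child seed plus a jittered contrast,
    so masks differ across patients while the whole cohort is reproducible
    from ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    spec_template.validate()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_patients):
        child_seed = int(rng.integers(0, 2**31 - 1))
        jitter = rng.uniform(0.85, 1.15, size=len(spec_template.tumor_contrast))
        contrast = tuple(c * j for c, j in zip(spec_template.tumor_contrast, jitter))
        spec = replace(spec_template, seed=child_seed, tumor_contrast=contrast)
        vol, mask = generate_phantom(spec)
        vol = MultimodalVolume(vol.intensities, vol.spacing, patient_id=f"phantom-{i:03d}")
        cohort.append((vol, mask))
    return cohort


MODALITY_NAMES = ("flair", "t2", "t1", "t1ce")


def write_cohort(cohort, out_dir: str | Path, seed: int | None = None) -> Path:
    """Write a cohort as NIfTI files plus a JSON manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for vol, mask in cohort:
        names = MODALITY_NAMES[: vol.n_channels] if vol.n_channels <= 4 else tuple(
            f"ch{c}" for c in range(vol.n_channels)
        )
        paths = {}
        for c, name in enumerate(names):
            p = out_dir / f"{vol.patient_id}_{name}.nii.gz"
            write_volume(vol.intensities[c], vol.spacing, p)
            paths[name] = p.name
        mask_path = out_dir / f"{vol.patient_id}_mask.nii.gz"
        write_mask(mask, vol.spacing, mask_path)
        box = box_from_mask(mask) if mask.any() else None
        entries.append(
            {
                "patient_id": vol.patient_id,
                "modalities": paths,
                "mask": mask_path.name,
                "box": None if box is None else {"low": list(box.low), "high": list(box.high)},
            }
        )
    manifest = {"seed": seed, "patients": entries}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
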