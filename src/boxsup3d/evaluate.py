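"""Segmentation metrics, post-processing, the region-grow baseline, folds.

Dice measures volumetric overlap; the Hausdorff family measures boundary
agreement in millimetres.  The directed Hausdorff distance used here is the
max-min form — the largest distance from a point of one set to its nearest
point in the other — and Hausdorff95 replaces that max with the 95th
percentile, discounting isolated outlier voxels.  Distances are computed
between foreground voxel centers scaled by the voxel spacing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from collections import deque
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class SegmentationResult:
    """Probability map plus its thresholded binary mask."""

    probability: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    threshold: float = 0.5
    patient_id: str = "unknown"

    @property
    def mask(self) -> np.ndarray:
        return np.asarray(self.probability) >= self.threshold


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks score 1.0 by convention."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    pts = np.argwhere(np.asarray(mask, dtype=bool))
    return pts * np.asarray(spacing, dtype=np.float64)


def _directed_nearest(a_pts: np.ndarray, b_pts: np.ndarray) -> np.ndarray:
    """Distance from each point of A to its nearest point in B (mm)."""
    tree = cKDTree(b_pts)
    d, _ = tree.query(a_pts, k=1)
    return d


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one 6-neighbor background voxel."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return mask & ~eroded


def directed_hausdorff(a, b, spacing=(1.0, 1.0, 1.0), surface_only: bool = False) -> float:
    """max over a in A of the distance to the nearest b in B, in mm.

    Returns NaN (a missing value, never 0) when either set is empty.
    """
    if surface_only:
        a, b = surface_voxels(a), surface_voxels(b)
    a_pts = _points_mm(a, spacing)
    b_pts = _points_mm(b, spacing)
    if len(a_pts) == 0 or len(b_pts) == 0:
        return math.nan
    return float(_directed_nearest(a_pts, b_pts).max())


def hausdorff(a, b, spacing=(1.0, 1.0, 1.0), surface_only: bool = False) -> float:
    """Symmetric Hausdorff distance: max of the two directed distances."""
    return max(
        directed_hausdorff(a, b, spacing, surface_only),
        directed_hausdorff(b, a, spacing, surface_only),
    )


def hausdorff95(a, b, spacing=(1.0, 1.0, 1.0), surface_only: bool = False) -> float:
    """Max of the two directed 95th-percentile nearest distances (mm).

    Percentiles use linear interpolation between order statistics, so
    hausdorff95 <= hausdorff always holds.
    """
    if surface_only:
        a, b = surface_voxels(a), surface_voxels(b)
    a_pts = _points_mm(a, spacing)
    b_pts = _points_mm(b, spacing)
    if len(a_pts) == 0 or len(b_pts) == 0:
        return math.nan
    d_ab = np.percentile(_directed_nearest(a_pts, b_pts), 95)
    d_ba = np.percentile(_directed_nearest(b_pts, a_pts), 95)
    return float(max(d_ab, d_ba))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior cavities (6-connectivity); never removes foreground."""
    return ndimage.binary_fill_holes(
        np.asarray(mask, dtype=bool),
        structure=ndimage.generate_binary_structure(3, 1),
    )


def region_grow_baseline(
    volume: np.ndarray,
    seed_point,
    threshold: float = 0.5,
    channel: int = 0,
) -> np.ndarray:
    """Learning-free flood-fill baseline on one (normalized) channel.

    Starting from ``seed_point``, 6-connected neighbors are admitted while
    their absolute intensity difference from the running region mean stays
    strictly below ``threshold`` (gray-level discontinuity criterion).
    ``volume`` may be (C, X, Y, Z) or a single (X, Y, Z) channel.
    """
    vol = np.asarray(volume)
    ch = vol[channel] if vol.ndim == 4 else vol
    seed_point = tuple(int(c) for c in seed_point)
    if any(not 0 <= c < s for c, s in zip(seed_point, ch.shape)):
        raise ValueError(f"seed {seed_point} outside volume {ch.shape}")
    if ch[seed_point] == 0:
        raise ValueError("seed lies on zero background outside the brain")
    mask = np.zeros(ch.shape, dtype=bool)
    mask[seed_point] = True
    total = float(ch[seed_point])
    count = 1
    queue = deque([seed_point])
    neighbors = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while queue:
        x, y, z = queue.popleft()
        mean = total / count
        for dx, dy, dz in neighbors:
            p = (x + dx, y + dy, z + dz)
            if any(not 0 <= c < s for c, s in zip(p, ch.shape)):
                continue
            if mask[p]:
                continue
            if abs(float(ch[p]) - mean) < threshold:
                mask[p] = True
                total += float(ch[p])
                count += 1
                queue.append(p)
    return mask


@dataclass
class MetricsReport:
    """Per-volume metrics plus fold-aggregated cohort statistics."""

    per_volume: pd.DataFrame
    folds: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "summary": self.summary,
            "folds": self.folds.to_dict(orient="records"),
            "per_volume": self.per_volume.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    def to_csv(self, path: str | Path) -> None:
        self.per_volume.to_csv(path, index=False)


METRIC_NAMES = ("dice", "hausdorff", "hausdorff95")


def evaluate_volumes(results, ground_truths, post_process: bool = True) -> pd.DataFrame:
    """Per-volume metric table; predictions get hole-filling first."""
    rows = []
    for res, gt in zip(results, ground_truths):
        pred = res.mask
        if post_process:
            pred = fill_holes(pred)
        gt = np.asarray(gt, dtype=bool)
        if pred.shape != gt.shape:
            raise ValueError(f"prediction {pred.shape} vs truth {gt.shape}")
        rows.append(
            {
                "patient_id": res.patient_id,
                "dice": dice(pred, gt) if gt.any() or pred.any() else 1.0,
                "hausdorff": hausdorff(pred, gt, res.spacing),
                "hausdorff95": hausdorff95(pred, gt, res.spacing),
                "pred_volume": int(pred.sum()),
                "gt_volume": int(gt.sum()),
            }
        )
    return pd.DataFrame(rows)


def evaluate_cohort(
    results,
    ground_truths,
    n_folds: int = 5,
    split: float = 0.8,
    seed: int = 0,
    post_process: bool = True,
) -> MetricsReport:
    """Fold-aggregated cohort evaluation.

    Draws ``n_folds`` independent seeded 80/20 splits of the cohort,
    computes metrics over each evaluation subset, and reports per-metric
    mean +/- std across folds.  Hausdorff values that are undefined (empty
    prediction or truth) are excluded from fold means with their count
    reported; an empty prediction against a nonempty truth scores Dice 0.
    """
    if len(results) != len(ground_truths):
        raise ValueError("results and ground_truths must pair up")
    if len(results) < 5:
        raise ValueError("cohort evaluation needs at least 5 patients")
    per_volume = evaluate_volumes(results, ground_truths, post_process)
    rng = np.random.default_rng(seed)
    n = len(results)
    n_eval = max(n - int(round(split * n)), 1)
    fold_rows = []
    for fold in range(n_folds):
        eval_idx = rng.choice(n, size=n_eval, replace=False)
        sub = per_volume.iloc[sorted(eval_idx)]
        has_tumor = sub["gt_volume"] > 0
        if not has_tumor.any():
            import warnings

            warnings.warn(f"fold {fold}: no tumor-bearing evaluation volume, skipped")
            continue
        row = {"fold": fold, "n_eval": len(sub)}
        for m in METRIC_NAMES:
            vals = sub[m].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            row[f"{m}_mean"] = float(vals[ok].mean()) if ok.any() else math.nan
            row[f"{m}_missing"] = int((~ok).sum())
        fold_rows.append(row)
    folds = pd.DataFrame(fold_rows)
    summary = {}
    for m in METRIC_NAMES:
        col = folds[f"{m}_mean"].to_numpy(dtype=float) if len(folds) else np.array([])
        ok = np.isfinite(col)
        summary[m] = {
            "mean": float(col[ok].mean()) if ok.any() else math.nan,
            "std": float(col[ok].std()) if ok.any() else math.nan,
            "n_folds": int(ok.sum()),
        }
    return MetricsReport(per_volume=per_volume, folds=folds, summary=summary)
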