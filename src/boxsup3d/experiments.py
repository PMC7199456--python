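"""Canned desk-scale experiments: PU vs naive vs region grow on phantoms.

These drive the package's own validation: a seeded phantom cohort is
generated, the segmentation network is trained once per objective under one
shared configuration, and held-out volumes are scored.  Sizes are the desk
scale discussed in ``docs/methods.md``.
"""

from __future__ import annotations

import numpy as np

from .evaluate import SegmentationResult, dice, evaluate_volumes, region_grow_baseline
from .model import BoxSupModel
from .patch_sampler import SamplerConfig
from .phantom import PhantomSpec, generate_cohort
from .trainer import TrainConfig
from .volume_io import box_from_mask, normalize_volume


def desk_study(
    seed: int,
    n_patients: int = 12,
    n_test: int = 3,
    n_patches: int = 100,
    epochs: int = 3,
    n_seeds: int = 2,
    learning_rate: float = 1e-3,
    batch_size: int = 8,
    modes: tuple[str, ...] = ("pu", "naive"),
) -> dict:
    """Train each objective on a shared phantom cohort; score held-out volumes.

    Returns per-mode held-out Dice / Hausdorff95 (mean over test volumes and
    training seeds) and the predicted-to-true volume ratio, a direct readout
    of over-segmentation toward the box.
    """
    rng = np.random.default_rng(seed)
    cohort_seed = int(rng.integers(0, 2**31 - 1))
    cohort = generate_cohort(n_patients, PhantomSpec(), seed=cohort_seed)
    vols = [v for v, _ in cohort]
    masks = [m for _, m in cohort]
    boxes = [box_from_mask(m) for m in masks]
    train_idx = list(range(n_patients - n_test))
    test_idx = list(range(n_patients - n_test, n_patients))

    out: dict = {mode: {"dice": [], "hausdorff95": [], "volume_ratio": []} for mode in modes}
    train_seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(n_seeds)]
    for train_seed in train_seeds:
        for mode in modes:
            model = BoxSupModel(
                [vols[i] for i in train_idx],
                [boxes[i] for i in train_idx],
                sampler_cfg=SamplerConfig(n_selected=n_patches, seed=train_seed),
                train_cfg=TrainConfig(
                    epochs=epochs,
                    mode=mode,
                    seed=train_seed,
                    learning_rate=learning_rate,
                    batch_size=batch_size,
                ),
            )
            results = model.fit()
            segs = [
                SegmentationResult(
                    results.predict(vols[i]), vols[i].spacing, patient_id=vols[i].patient_id
                )
                for i in test_idx
            ]
            df = evaluate_volumes(segs, [masks[i] for i in test_idx])
            out[mode]["dice"].append(float(df["dice"].mean()))
            hd95 = df["hausdorff95"].to_numpy(dtype=float)
            out[mode]["hausdorff95"].append(float(np.nanmean(hd95)))
            out[mode]["volume_ratio"].append(
                float((df["pred_volume"] / df["gt_volume"]).mean())
            )
    summary = {
        mode: {k: float(np.mean(v)) for k, v in metrics.items()}
        for mode, metrics in out.items()
    }
    summary["held_out_patients"] = n_test
    summary["train_seeds"] = train_seeds
    summary["cohort_seed"] = cohort_seed
    return summary


def region_grow_study(seed: int, n_patients: int = 8) -> dict:
    """Score the learning-free region-grow baseline on a phantom cohort."""
    cohort = generate_cohort(n_patients, PhantomSpec(), seed=seed)
    scores = []
    for vol, mask in cohort:
        box = box_from_mask(mask)
        center = tuple((l + h) // 2 for l, h in zip(box.low, box.high))
        nv = normalize_volume(vol)
        grown = region_grow_baseline(nv.intensities, center, threshold=0.5)
        scores.append(dice(grown, mask))
    return {"dice": float(np.mean(scores)), "n_patients": n_patients}
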