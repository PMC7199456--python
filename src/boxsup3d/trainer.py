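"""Mini-batch training with the nnPU gradient switch, and whole-volume inference.

Each step decomposes the batch into the three empirical risk terms.  While
the correction term r_u_minus - pi_p * r_p_minus stays above -beta the
optimizer follows the gradient of the PU objective with step scale eta;
once it drops below -beta — the signature of the network overfitting the
unlabeled box region — the step instead *maximizes* the correction term
(gradient of pi_p*r_p_minus - r_u_minus) with the discounted scale
gamma * eta.  ``mode="naive"`` bypasses all of this and trains plain
cross-entropy on the box labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, UNet3D
from .patch_sampler import PatchSample, SamplerConfig
from .pu_risk import (
    PULossConfig,
    defensive_gradient,
    naive_gradient,
    naive_risk,
    nn_pu_risk,
    pu_risk,
    pu_risk_gradient,
    risk_components,
    sigmoid,
)
from .volume_io import MultimodalVolume


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; ``mode`` selects the PU or the naive objective."""

    batch_size: int = 8
    epochs: int = 3
    learning_rate: float = 1e-3
    mode: str = "pu"
    pu_cfg: PULossConfig = field(default_factory=PULossConfig)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mode not in ("pu", "naive"):
            raise ValueError(f"mode must be 'pu' or 'naive', got {self.mode}")


@dataclass
class TrainHistory:
    """Per-step records plus optional per-epoch validation Dice."""

    steps: list[dict] = field(default_factory=list)
    epoch_val_dice: list[float] = field(default_factory=list)

    def append(self, **record) -> None:
        self.steps.append(record)

    def n_defensive_steps(self) -> int:
        return sum(1 for s in self.steps if s.get("branch") == "defensive")

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.steps:
                fh.write(json.dumps(s) + "\n")


def _stack_batch(samples: list[PatchSample]):
    x = np.stack([s.features for s in samples]).astype(np.float32)
    y = np.stack([s.label_volume for s in samples]).astype(np.int8)
    return x, y


def train_step(
    net: UNet3D, opt: Adam, x: np.ndarray, y: np.ndarray, cfg: TrainConfig
) -> dict:
    """One optimizer update on a stacked batch; returns the step record."""
    pu = cfg.pu_cfg
    net.zero_grad()
    logits = net.forward(x, train=True)
    flat_logits = logits[:, 0]
    record: dict = {}
    if cfg.mode == "naive":
        objective = naive_risk(flat_logits, y)
        dlogits = naive_gradient(flat_logits, y)
        record.update(objective=objective, branch="naive")
        lr_scale = pu.eta
    else:
        comps = risk_components(flat_logits, y, shared_n=pu.shared_n)
        risk_nn, defensive = nn_pu_risk(comps, pu)
        record.update(
            r_p_plus=comps.r_p_plus,
            r_u_minus=comps.r_u_minus,
            r_p_minus=comps.r_p_minus,
            objective=risk_nn,
            pu_risk=pu_risk(comps, pu),
        )
        if defensive:
            dlogits = defensive_gradient(flat_logits, y, pu)
            lr_scale = pu.gamma * pu.eta
            record.update(branch="defensive", lr_scale=lr_scale)
        else:
            dlogits = pu_risk_gradient(flat_logits, y, pu)
            lr_scale = pu.eta
            record.update(branch="pu", lr_scale=lr_scale)
    if not np.isfinite(record["objective"]):
        raise FloatingPointError(f"non-finite objective at step {opt.t}: {record}")
    net.backward(dlogits[:, None].astype(logits.dtype))
    opt.step(net.gradients(), lr_scale=lr_scale)
    return record


def train(
    samples: list[PatchSample],
    net: UNet3D,
    cfg: TrainConfig,
    validate=None,
) -> tuple[UNet3D, TrainHistory]:
    """Algorithm: shuffle into mini-batches each epoch, step per batch.

    ``validate`` may be a callable ``net -> float`` (e.g. held-out Dice)
    evaluated after each epoch for reporting only; it never contributes
    gradients, so ground-truth masks stay out of training.
    """
    tags = {s.region_tag for s in samples}
    if cfg.mode == "pu" and tags != {"S0", "S1"}:
        raise ValueError("training set must contain both S1 and S0 patches")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    n = len(samples)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            batch = [samples[i] for i in order[start : start + cfg.batch_size]]
            x, y = _stack_batch(batch)
            if cfg.mode == "pu" and (y.min() == y.max()):
                continue  # degenerate single-class batch; skip, sampler mixing makes this rare
            record = train_step(net, opt, x, y, cfg)
            record.update(epoch=epoch, step=opt.t)
            history.append(**record)
        if validate is not None:
            history.epoch_val_dice.append(float(validate(net)))
    return net, history


def _tile_lows(side: int, d: int, stride: int) -> list[int]:
    lows = list(range(0, side - d + 1, stride))
    if lows[-1] != side - d:
        lows.append(side - d)
    return lows


def predict_volume(
    net: UNet3D,
    vol: MultimodalVolume,
    sampler_cfg: SamplerConfig,
    batch_size: int = 8,
    mask_background: bool = True,
) -> np.ndarray:
    """Sliding-window probability map over a full (normalized) volume.

    Tiles the volume with multiscale patches at stride d/2 and averages the
    sigmoid probabilities where tiles overlap; returns float32 in [0, 1]
    at full resolution.  With ``mask_background`` (default), voxels that are
    exactly 0 in every channel — outside the brain by construction — get
    probability 0: on such voxels the input carries no signal at all and
    the network output degenerates to its bias, which is not a prediction.
    """
    from .patch_sampler import build_multiscale_input

    d = sampler_cfg.patch_size
    shape = vol.shape
    if any(s < d for s in shape):
        raise ValueError(f"volume {shape} smaller than patch side {d}")
    stride = max(d // 2, 1)
    lows = [_tile_lows(s, d, stride) for s in shape]
    centers = [
        (lx + d // 2, ly + d // 2, lz + d // 2)
        for lx in lows[0]
        for ly in lows[1]
        for lz in lows[2]
    ]
    prob_sum = np.zeros(shape, dtype=np.float64)
    count = np.zeros(shape, dtype=np.int32)
    for i in range(0, len(centers), batch_size):
        chunk = centers[i : i + batch_size]
        x = np.stack([build_multiscale_input(vol, c, sampler_cfg) for c in chunk])
        logits = net.forward(x, train=False)
        probs = sigmoid(logits[:, 0])
        for c, p in zip(chunk, probs):
            sl = tuple(slice(ci - d // 2, ci - d // 2 + d) for ci in c)
            prob_sum[sl] += p
            count[sl] += 1
    prob = (prob_sum / count).astype(np.float32)
    if mask_background:
        prob[np.all(vol.intensities == 0, axis=0)] = 0.0
    return prob
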