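"""Model/Results interface tying the pipeline together.

``BoxSupModel`` is built from a cohort of multimodal volumes with box
annotations (the weak labels); ``fit()`` normalizes, samples patches,
trains the network under the chosen objective and returns a
``BoxSupResults`` holding the trained parameters, the optimization history
and prediction/evaluation methods, with a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluate import MetricsReport, SegmentationResult, evaluate_cohort
from .nn import NetworkConfig, UNet3D, build_network
from .patch_sampler import SamplerConfig, sample_patches
from .trainer import TrainConfig, TrainHistory, predict_volume, train
from .volume_io import BoxAnnotation, MultimodalVolume, normalize_volume


@dataclass
class BoxSupModel:
    """Weakly supervised segmentation model over a cohort.

    Parameters
    ----------
    volumes : list of MultimodalVolume
        Raw (un-normalized) studies.
    boxes : list of BoxAnnotation
        One 3D box per study; the only supervision used for fitting.
    sampler_cfg, network_cfg, train_cfg
        Stage configurations; defaults are the desk scale.
    """

    volumes: list
    boxes: list
    sampler_cfg: SamplerConfig = field(default_factory=SamplerConfig)
    network_cfg: NetworkConfig | None = None
    train_cfg: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if len(self.volumes) != len(self.boxes):
            raise ValueError("need one box annotation per volume")
        if self.network_cfg is None:
            n_mod = self.volumes[0].n_channels
            self.network_cfg = NetworkConfig(
                in_channels=2 * n_mod, patch_size=self.sampler_cfg.patch_size
            )
        if self.network_cfg.patch_size != self.sampler_cfg.patch_size:
            raise ValueError("network and sampler patch sizes differ")

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs) -> "BoxSupModel":
        """Build from a cohort manifest written by the phantom module."""
        import json
        from pathlib import Path

        from .volume_io import read_volume

        manifest_path = Path(manifest_path)
        root = manifest_path.parent
        manifest = json.loads(manifest_path.read_text())
        volumes, boxes = [], []
        for entry in manifest["patients"]:
            paths = {m: root / p for m, p in entry["modalities"].items()}
            volumes.append(read_volume(paths, patient_id=entry["patient_id"]))
            b = entry["box"]
            if b is None:
                raise ValueError(f"{entry['patient_id']}: no box annotation in manifest")
            boxes.append(BoxAnnotation(low=tuple(b["low"]), high=tuple(b["high"])))
        return cls(volumes, boxes, **kwargs)

    def normalized_volumes(self) -> list:
        return [normalize_volume(v) for v in self.volumes]

    def sample_training_patches(self, volumes=None) -> list:
        volumes = self.normalized_volumes() if volumes is None else volumes
        rng = np.random.default_rng(self.sampler_cfg.seed)
        patches = []
        for vol, box in zip(volumes, self.boxes):
            cfg = replace(self.sampler_cfg, seed=int(rng.integers(0, 2**31 - 1)))
            patches.extend(sample_patches(vol, box, cfg))
        return patches

    def fit(self, mode: str | None = None, validate=None) -> "BoxSupResults":
        """Train under ``mode`` ('pu' or 'naive'); returns results object."""
        train_cfg = self.train_cfg if mode is None else replace(self.train_cfg, mode=mode)
        net = build_network(self.network_cfg, seed=train_cfg.seed)
        patches = self.sample_training_patches()
        net, history = train(patches, net, train_cfg, validate=validate)
        return BoxSupResults(model=self, network=net, history=history, train_cfg=train_cfg)


@dataclass
class BoxSupResults:
    """Fitted segmentation network plus training diagnostics."""

    model: BoxSupModel
    network: UNet3D
    history: TrainHistory
    train_cfg: TrainConfig

    def predict(self, vol: MultimodalVolume, normalized: bool = False) -> np.ndarray:
        """Probability volume for one study (normalizes unless told not to)."""
        if not normalized:
            vol = normalize_volume(vol)
        return predict_volume(self.network, vol, self.model.sampler_cfg)

    def predict_cohort(self, volumes=None, normalized: bool = False) -> list:
        volumes = self.model.volumes if volumes is None else volumes
        out = []
        for v in volumes:
            prob = self.predict(v, normalized=normalized)
            out.append(SegmentationResult(prob, v.spacing, patient_id=v.patient_id))
        return out

    def evaluate(self, ground_truths, volumes=None, **kwargs) -> MetricsReport:
        """Cohort metrics against voxel-level ground truth (evaluation only)."""
        results = self.predict_cohort(volumes=volumes)
        return evaluate_cohort(results, ground_truths, **kwargs)

    def summary(self, report: MetricsReport | None = None) -> str:
        """Plain-text summary of the fit (statsmodels-style table)."""
        buf = io.StringIO()
        cfg = self.train_cfg
        steps = self.history.steps
        w = 58
        line = "=" * w
        buf.write(line + "\n")
        buf.write("Box-supervised PU segmentation results".center(w) + "\n")
        buf.write(line + "\n")
        rows = [
            ("objective", cfg.mode),
            ("patients", len(self.model.volumes)),
            ("patches/patient", self.model.sampler_cfg.n_selected),
            ("patch side", self.model.sampler_cfg.patch_size),
            ("epochs", cfg.epochs),
            ("optimizer steps", len(steps)),
            ("network parameters", self.network.n_params),
        ]
        if cfg.mode == "pu":
            rows += [
                ("class prior pi_p", cfg.pu_cfg.pi_p),
                ("defensive steps", self.history.n_defensive_steps()),
            ]
        if steps:
            rows.append(("final objective (nats)", f"{steps[-1]['objective']:.4f}"))
        if self.history.epoch_val_dice:
            rows.append(("last validation Dice", f"{self.history.epoch_val_dice[-1]:.4f}"))
        if report is not None:
            for m, s in report.summary.items():
                rows.append((f"{m} (mean +/- std over folds)", f"{s['mean']:.4f} +/- {s['std']:.4f}"))
        for k, v in rows:
            buf.write(f"{k:<34}{v!s:>24}\n")
        buf.write(line + "\n")
        return buf.getvalue()
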