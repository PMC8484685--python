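"""Model/Results facade over the pipeline, in the statsmodels idiom.

``TileSetClassifier`` is constructed from data (tile-set datasets plus a
label table) and an :class:`~panoptes.model_zoo.ArchitectureConfig`;
``fit()`` runs the training schedule and returns a :class:`FitResults`
carrying the trained network, the validation log, prediction tables and
evaluation reports, with a ``summary()`` table for quick reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluation
from .cohort import (
    ClassWeights,
    SplitAssignment,
    TileSetDataset,
    compute_class_weights,
    impute_clinical,
)
from .model_zoo import ArchitectureConfig, build_model
from .training import TrainSchedule, TrainingResult, train


class TileSetClassifier:
    """A Panoptes-family (or baseline) classifier bound to a cohort.

    Parameters
    ----------
    datasets : dict with "train"/"validation"/"test" TileSetDataset values
    labels : label table (for class weights / bookkeeping)
    split : the patient-level split that produced the datasets
    arch : architecture configuration
    seed : weight-initialization seed
    """

    def __init__(
        self,
        datasets: dict[str, TileSetDataset],
        labels: pd.DataFrame,
        split: SplitAssignment,
        arch: ArchitectureConfig,
        seed: int = 0,
    ):
        self.datasets = datasets
        self.labels = labels
        self.split = split
        self.arch = arch
        self.seed = seed
        if arch.use_clinical and datasets["train"].clinical is None:
            impute_clinical(
                datasets["train"], datasets["validation"], datasets["test"]
            )
        self.network = build_model(arch, seed)
        tile_counts: dict[str, int] = {}
        for part in datasets.values():
            sid, cnt = np.unique(part.slide_ids, return_counts=True)
            tile_counts.update(dict(zip(sid, cnt.astype(int))))
        self.class_weights: ClassWeights = compute_class_weights(
            labels, split.task, split, tile_counts
        )

    @classmethod
    def from_manifest(
        cls,
        manifest_path: str,
        labels: pd.DataFrame,
        split: SplitAssignment,
        arch: ArchitectureConfig,
        input_px: Optional[int] = None,
        seed: int = 0,
    ) -> "TileSetClassifier":
        datasets = {
            part: TileSetDataset.from_records(
                manifest_path, part, input_px or arch.input_px
            )
            for part in ("train", "validation", "test")
        }
        return cls(datasets, labels, split, arch, seed)

    def fit(self, schedule: Optional[TrainSchedule] = None) -> "FitResults":
        schedule = schedule or TrainSchedule(
            batch_size=24 if self.arch.is_panoptes else 64, seed=self.seed
        )
        result = train(
            self.network,
            self.datasets["train"],
            self.datasets["validation"],
            schedule,
            self.class_weights,
        )
        return FitResults(self, schedule, result)


@dataclass
class FitResults:
    model: TileSetClassifier
    schedule: TrainSchedule
    training: TrainingResult
    _pred_cache: dict = field(default_factory=dict)

    def predict(self, partition: str = "test") -> pd.DataFrame:
        if partition not in self._pred_cache:
            self._pred_cache[partition] = evaluation.predictions_from_model(
                self.model.network, self.model.datasets[partition]
            )
        return self._pred_cache[partition]

    def evaluate(
        self,
        partition: str = "test",
        level: str = "per_patient",
        n_boot: int = 1000,
        seed: int = 0,
    ) -> evaluation.MetricsReport:
        return evaluation.compute_metrics(
            self.predict(partition), level=level, n_boot=n_boot, seed=seed
        )

    def features(self, partition: str = "test") -> np.ndarray:
        from .model_zoo import forward_features

        ds = self.model.datasets[partition]
        use_clin = self.model.network.clinical is not None
        chunks = []
        for i in range(0, len(ds), 64):
            idx = np.arange(i, min(i + 64, len(ds)))
            chunks.append(
                forward_features(self.model.network, ds.batch(idx, clinical=use_clin))
            )
        return np.concatenate(chunks, axis=0)

    def summary(self, n_boot: int = 200, seed: int = 0) -> str:
        """Human-readable fit summary with test metrics at both levels."""
        m = self.model
        lines = [
            "Tile-set classifier fit",
            "=" * 60,
            f"architecture:        {m.arch.family}"
            + (" + clinical" if m.arch.use_clinical else ""),
            f"width multiplier:    {m.arch.width_multiplier}",
            f"input size:          {m.arch.input_px} px",
            f"parameters:          {m.network.n_params():,}",
            f"task:                {m.split.task} ({m.split.mode} split)",
            f"class weights:       ({m.class_weights.weights[0]:.3f}, "
            f"{m.class_weights.weights[1]:.3f})",
            f"train/val/test sets: {len(m.datasets['train'])}/"
            f"{len(m.datasets['validation'])}/{len(m.datasets['test'])} tile sets",
            f"best iteration:      {self.training.best_iteration} "
            f"(val loss {self.training.best_val_loss:.4f})"
            if self.training.best_iteration
            else "best iteration:      none (no checkpoint)",
            "-" * 60,
        ]
        for level in ("per_patient", "per_tile"):
            rep = self.evaluate(level=level, n_boot=n_boot, seed=seed)
            ci = (
                f" (95% CI {rep.auroc_ci[0]:.3f}-{rep.auroc_ci[1]:.3f})"
                if rep.auroc_ci
                else ""
            )
            auc = f"{rep.auroc:.3f}" if rep.auroc is not None else "undefined"
            lines.append(
                f"{level:12s} AUROC {auc}{ci}  "
                f"acc {rep.accuracy:.3f}  n+={rep.n_pos} n-={rep.n_neg}"
            )
        return "\n".join(lines)
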