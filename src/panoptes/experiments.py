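"""Desk-scale study harnesses built from the pipeline pieces.

The central experiment is multi-resolution signal recovery: on a synthetic
cohort whose class signal lives only at macro (2.5x-visible) scale, a
Panoptes model should recover the labels of held-out patients while a
10x-only baseline should not; on a null cohort neither should.  The harness
keeps memory flat by rendering, tiling and downsampling one slide at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import TileSetDataset, make_split
from .model import FitResults, TileSetClassifier
from .model_zoo import ArchitectureConfig
from .synthetic_data import generate_cohort, render_slide
from .tiling import TileFilterConfig, tile_slide
from .training import TrainSchedule

#: study conditions of the desk-scale signal-recovery experiment
DESK_N_PATIENTS = 40
DESK_EXTENT = (2392, 2392)
DESK_INPUT_PX = 75
DESK_WIDTH = 0.1
DESK_ITERATIONS = 600
DESK_LR = 1e-3


def _concat_datasets(parts: Sequence[TileSetDataset]) -> TileSetDataset:
    return TileSetDataset(
        x={m: np.concatenate([p.x[m] for p in parts]) for m in parts[0].x},
        labels=np.concatenate([p.labels for p in parts]),
        clinical_raw=np.concatenate([p.clinical_raw for p in parts]),
        patient_ids=np.concatenate([p.patient_ids for p in parts]),
        slide_ids=np.concatenate([p.slide_ids for p in parts]),
        tile_set_ids=np.concatenate([p.tile_set_ids for p in parts]),
        anchors=np.concatenate([p.anchors for p in parts]),
    )


def subset_dataset(ds: TileSetDataset, mask: np.ndarray) -> TileSetDataset:
    return TileSetDataset(
        x={m: ds.x[m][mask] for m in ds.x},
        labels=ds.labels[mask],
        clinical_raw=ds.clinical_raw[mask],
        patient_ids=ds.patient_ids[mask],
        slide_ids=ds.slide_ids[mask],
        tile_set_ids=ds.tile_set_ids[mask],
        anchors=ds.anchors[mask],
        clinical=None if ds.clinical is None else ds.clinical[mask],
    )


def build_cohort_datasets(
    n_patients: int = DESK_N_PATIENTS,
    effect: float = 1.0,
    signal_scale: str = "macro",
    seed: int = 1,
    extent: tuple[int, int] = DESK_EXTENT,
    input_px: int = DESK_INPUT_PX,
    stain_mode: str = "tile",
    task: str = "subtype",
    split_mode: str = "mixed",
) -> tuple[dict[str, TileSetDataset], pd.DataFrame, "object"]:
    """Render a cohort slide by slide into partitioned datasets.

    Returns (datasets dict keyed by partition, label table, split).
    """
    specs, labels = generate_cohort(
        n_patients,
        signal_scale=signal_scale,
        effect=effect,
        seed=seed,
        extent=extent,
        task=task,
    )
    split = make_split(labels, task, split_mode, seed=seed)
    label_of = dict(zip(labels["patient_id"], labels[task]))
    clin_of = {
        r.patient_id: (r.age, r.bmi) for r in labels.itertuples()
    }
    cfg = TileFilterConfig()
    per_slide: list[TileSetDataset] = []
    for sp in specs:
        slide, _mask = render_slide(sp)
        sets: list = []
        tile_slide(
            slide,
            cfg,
            sink=sets.append,
            patient_id=sp.patient_id,
            stain_mode=stain_mode,
        )
        if sets:
            per_slide.append(
                TileSetDataset.from_tile_sets(
                    sets,
                    lambda p: int(label_of[p]),
                    input_px=input_px,
                    clinical_of=lambda p: clin_of[p],
                )
            )
    full = _concat_datasets(per_slide)
    part = np.array([split.partition_of(p) or "none" for p in full.patient_ids])
    datasets = {
        name: subset_dataset(full, part == name)
        for name in ("train", "validation", "test")
    }
    return datasets, labels, split


def desk_schedule(
    is_panoptes: bool,
    seed: int,
    iterations: int = DESK_ITERATIONS,
    learning_rate: float = DESK_LR,
) -> TrainSchedule:
    """The full-scale schedule with every counter scaled to a CPU desk run."""
    return TrainSchedule(
        batch_size=24 if is_panoptes else 64,
        learning_rate=learning_rate,
        validate_every=100,
        validate_batches=8,
        min_iter_for_lossmin_validation=iterations * 10,  # disabled at this scale
        early_stop_patience=400,
        min_iter_before_stop=iterations,
        max_iterations=iterations,
        seed=seed,
    )


def fit_on_cohort(
    datasets: dict[str, TileSetDataset],
    labels: pd.DataFrame,
    split,
    family: str = "panoptes1",
    seed: int = 1,
    iterations: int = DESK_ITERATIONS,
    width_multiplier: float = DESK_WIDTH,
    input_px: int = DESK_INPUT_PX,
    use_clinical: bool = False,
) -> FitResults:
    arch = ArchitectureConfig(
        family=family,
        width_multiplier=width_multiplier,
        input_px=input_px,
        use_clinical=use_clinical,
    )
    clf = TileSetClassifier(datasets, labels, split, arch, seed=seed)
    return clf.fit(desk_schedule(arch.is_panoptes, seed, iterations))


@dataclass
class SignalRecoveryResult:
    panoptes_macro: FitResults
    baseline_macro: FitResults
    panoptes_null: FitResults

    def headline(self, n_boot: int = 1000, seed: int = 0) -> dict:
        out = {}
        for name, fit in (
            ("panoptes_macro", self.panoptes_macro),
            ("baseline_macro", self.baseline_macro),
            ("panoptes_null", self.panoptes_null),
        ):
            rep = fit.evaluate(level="per_patient", n_boot=n_boot, seed=seed)
            tile = fit.evaluate(level="per_tile", n_boot=min(n_boot, 200), seed=seed)
            out[name] = {
                "patient_auroc": rep.auroc,
                "patient_auroc_ci": rep.auroc_ci,
                "tile_auroc": tile.auroc,
            }
        return out


def signal_recovery_experiment(
    seed: int = 1,
    effect: float = 1.0,
    iterations: int = DESK_ITERATIONS,
    n_patients: int = DESK_N_PATIENTS,
) -> SignalRecoveryResult:
    """Run the full three-arm study: Panoptes/baseline on macro, Panoptes on null."""
    macro, labels_m, split_m = build_cohort_datasets(
        n_patients, effect=effect, signal_scale="macro", seed=seed
    )
    pan = fit_on_cohort(macro, labels_m, split_m, "panoptes1", seed, iterations)
    base = fit_on_cohort(
        macro, labels_m, split_m, "inception_resnet_v1", seed, iterations
    )
    del macro
    null, labels_n, split_n = build_cohort_datasets(
        n_patients, effect=0.0, signal_scale="macro", seed=seed
    )
    pan_null = fit_on_cohort(null, labels_n, split_n, "panoptes1", seed, iterations)
    return SignalRecoveryResult(pan, base, pan_null)
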