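"""Declarative run configuration and the staged pipeline driver.

A :class:`RunConfig` serializes to one JSON document whose sha256 digest is
the *run fingerprint*; every artifact directory gets stamped with it, each
stage records a completion marker, and re-running with an identical config
skips completed stages.  A changed config changes the fingerprint and
invalidates every downstream stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import evaluation, visualization
from .cohort import (
    TileSetDataset,
    load_label_table,
    make_split,
    write_records,
)
from .errors import PipelineStageError
from .model import TileSetClassifier
from .model_zoo import ArchitectureConfig, load_checkpoint, save_checkpoint
from .slide_io import open_slide
from .stain import StainProfile
from .synthetic_data import generate_cohort, generate_slide
from .tiling import TileFilterConfig, tile_slide
from .training import TrainSchedule

log = logging.getLogger("panoptes")


def _jsonl_logger(out_root: Path, fingerprint: str):
    def emit(stage: str, message: str, **kw):
        rec = {"stage": stage, "level": "info", "message": message,
               "fingerprint": fingerprint[:12], **kw}
        line = json.dumps(rec, sort_keys=True, default=str)
        log.info(line)
        with open(out_root / "pipeline.log.jsonl", "a") as f:
            f.write(line + "\n")

    return emit


@dataclass
class SimulateConfig:
    n_patients: int = 20
    slides_per_patient: int = 1
    class_balance: float = 0.5
    signal_scale: str = "macro"
    effect: float = 1.0
    extent: tuple[int, int] = (1196, 1196)
    margin_fraction: float = 0.0
    n_contaminants: int = 0
    task: str = "subtype"


@dataclass
class RunConfig:
    """All stage configurations plus the global seed and output root."""

    out_root: str = "panoptes-run"
    seed: int = 0
    input_px: int = 75
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    tile: TileFilterConfig = field(default_factory=TileFilterConfig)
    stain_mode: str = "tile"
    split_mode: str = "mixed"
    arch: ArchitectureConfig = field(
        default_factory=lambda: ArchitectureConfig(
            family="panoptes1", width_multiplier=0.1, input_px=75
        )
    )
    schedule: TrainSchedule = field(
        default_factory=lambda: TrainSchedule(
            validate_every=50,
            validate_batches=4,
            min_iter_for_lossmin_validation=10000,
            early_stop_patience=200,
            min_iter_before_stop=200,
            max_iterations=200,
            learning_rate=1e-3,
        )
    )
    n_boot: int = 200

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        return cls(
            out_root=d.get("out_root", "panoptes-run"),
            seed=d.get("seed", 0),
            input_px=d.get("input_px", 75),
            simulate=SimulateConfig(**{**d.get("simulate", {}),
                                       "extent": tuple(d.get("simulate", {}).get("extent", (1196, 1196)))}),
            tile=TileFilterConfig(**d.get("tile", {})),
            stain_mode=d.get("stain_mode", "tile"),
            split_mode=d.get("split_mode", "mixed"),
            arch=ArchitectureConfig(**d.get("arch", {})),
            schedule=TrainSchedule(**d.get("schedule", {})),
            n_boot=d.get("n_boot", 200),
        )

    def fingerprint(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _stage_done(out: Path, stage: str, fp: str) -> bool:
    marker = out / f"{stage}.done.json"
    if marker.exists():
        try:
            return json.loads(marker.read_text())["fingerprint"] == fp
        except (json.JSONDecodeError, KeyError):
            return False
    return False


def _mark_done(out: Path, stage: str, fp: str, **extra) -> None:
    (out / f"{stage}.done.json").write_text(
        json.dumps({"fingerprint": fp, **extra}, sort_keys=True, default=str)
    )


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> split -> tile+records -> train -> evaluate -> visualize.

    Each stage is idempotent: completed stages (matching fingerprint) are
    skipped.  Any failure raises :class:`PipelineStageError` naming the
    stage and config digest.  Returns a dict of key artifact paths.
    """
    fp = config.fingerprint()
    out = Path(config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json())
    emit = _jsonl_logger(out, fp)
    artifacts: dict[str, str] = {"out_root": str(out), "fingerprint": fp}

    def stage(name):
        def deco(fn):
            def wrapped():
                if _stage_done(out, name, fp):
                    emit(name, "skipped (already complete)")
                    return
                emit(name, "started")
                try:
                    fn()
                except PipelineStageError:
                    raise
                except Exception as exc:
                    raise PipelineStageError(name, fp, str(exc)) from exc
                _mark_done(out, name, fp)
                emit(name, "finished")

            return wrapped

        return deco

    slides_dir = out / "slides"
    labels_csv = out / "labels.csv"
    records_dir = out / "records"
    manifest_path = records_dir / "manifest.json"
    ckpt_path = out / "checkpoint.npz"

    @stage("simulate")
    def _simulate():
        slides_dir.mkdir(exist_ok=True)
        sc = config.simulate
        specs, labels = generate_cohort(
            sc.n_patients,
            slides_per_patient=sc.slides_per_patient,
            class_balance=sc.class_balance,
            signal_scale=sc.signal_scale,
            effect=sc.effect,
            seed=config.seed,
            extent=tuple(sc.extent),
            margin_fraction=sc.margin_fraction,
            n_contaminants=sc.n_contaminants,
            task=sc.task,
        )
        for sp in specs:
            generate_slide(sp, str(slides_dir / f"{sp.slide_id}.tiff"))
        labels.to_csv(labels_csv, index=False)
        emit("simulate", f"wrote {len(specs)} slides")

    @stage("tile")
    def _tile():
        records_dir.mkdir(exist_ok=True)
        labels = load_label_table(str(labels_csv))
        split = make_split(labels, config.simulate.task, config.split_mode, config.seed)
        pid_of = dict(zip(labels["slide_id"], labels["patient_id"]))
        profile = StainProfile()

        def tile_sets():
            for f in sorted(slides_dir.glob("*.tiff")):
                slide = open_slide(str(f))
                sets: list = []
                summary = tile_slide(
                    slide,
                    config.tile,
                    stain_profile=profile,
                    sink=sets.append,
                    patient_id=pid_of[slide.slide_id],
                    stain_mode=config.stain_mode,
                )
                emit("tile", "slide tiled", **summary.as_dict())
                yield from sets

        write_records(
            tile_sets(), labels, split, str(records_dir), config_fingerprint=fp
        )

    @stage("train")
    def _train():
        labels = load_label_table(str(labels_csv))
        split = make_split(labels, config.simulate.task, config.split_mode, config.seed)
        clf = TileSetClassifier.from_manifest(
            str(manifest_path), labels, split, config.arch,
            input_px=config.input_px, seed=config.seed,
        )
        fit = clf.fit(config.schedule)
        save_checkpoint(str(ckpt_path), clf.network, config.arch)
        (out / "train_log.jsonl").write_text(fit.training.log_json())
        emit(
            "train",
            "training complete",
            best_iteration=fit.training.best_iteration,
            best_val_loss=fit.training.best_val_loss,
        )

    @stage("evaluate")
    def _evaluate():
        labels = load_label_table(str(labels_csv))
        split = make_split(labels, config.simulate.task, config.split_mode, config.seed)
        net = load_checkpoint(str(ckpt_path), config.arch, seed=config.seed)
        test = TileSetDataset.from_records(str(manifest_path), "test", config.input_px)
        preds = evaluation.predictions_from_model(net, test)
        preds.to_csv(out / "predictions_test.csv", index=False)
        reports = {}
        for level in ("per_patient", "per_tile"):
            rep = evaluation.compute_metrics(
                preds, level=level, n_boot=config.n_boot, seed=config.seed
            )
            reports[level] = rep.as_dict()
        (out / "metrics_test.json").write_text(json.dumps(reports, indent=2))
        emit("evaluate", "metrics written",
             per_patient_auroc=reports["per_patient"]["auroc"])

    @stage("visualize")
    def _visualize():
        from .model_zoo import forward_features

        net = load_checkpoint(str(ckpt_path), config.arch, seed=config.seed)
        test = TileSetDataset.from_records(str(manifest_path), "test", config.input_px)
        use_clin = net.clinical is not None
        feats, scores = [], []
        for i in range(0, len(test), 64):
            idx = np.arange(i, min(i + 64, len(test)))
            feats.append(forward_features(net, test.batch(idx, clinical=use_clin)))
            scores.append(net.predict_proba(test.batch(idx, clinical=use_clin))[:, 1])
        feats = np.concatenate(feats)
        scores = np.concatenate(scores)
        if len(feats) >= 10:
            emb = visualization.embed_features(
                feats, scores, tile_ids=test.tile_set_ids, seed=config.seed
            )
            visualization.render_embedding(emb, str(out / "tsne.png"))
        preds = pd.read_csv(out / "predictions_test.csv")
        slide_id = preds["slide_id"].iloc[0]
        slide = open_slide(str(slides_dir / f"{slide_id}.tiff"))
        hm = visualization.assemble_heatmap(preds, slide, tile_px=config.tile.tile_px)
        hm.to_csv(str(out / f"heatmap_{slide_id}.csv"))
        (out / f"heatmap_{slide_id}.json").write_text(hm.geometry_json())
        visualization.render_overlay(hm, slide, str(out / f"heatmap_{slide_id}.png"))

    for fn in (_simulate, _tile, _train, _evaluate, _visualize):
        fn()
    artifacts.update(
        manifest=str(manifest_path),
        checkpoint=str(ckpt_path),
        metrics=str(out / "metrics_test.json"),
        predictions=str(out / "predictions_test.csv"),
    )
    return artifacts
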