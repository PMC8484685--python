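"""Labels, per-patient splits, class weights, and the tile-set record store.

Labels are weak: a patient's subtype or mutation status is inherited by every
tile set cut from that patient's slides.  All partitioning therefore happens
at the *patient* level — slides of one patient never straddle partitions —
and class weights are computed over training tile sets so the loss reflects
the training data composition.

Tile sets are serialized into sharded length-prefixed binary records (JSON
header + raw tile bytes) under a JSON manifest carrying per-shard sha256
checksums and per-class counts, so a training run can verify and stream its
inputs reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ManifestError, SplitInfeasibleError
from .tiling import TileSet

PARTITIONS = ("train", "validation", "test")
REQUIRED_COLUMNS = ("patient_id", "slide_id", "cohort")
RESERVED = set(REQUIRED_COLUMNS) | {"age", "bmi"}


# -- label table ------------------------------------------------------------


def task_columns(labels: pd.DataFrame) -> list[str]:
    return [c for c in labels.columns if c not in RESERVED]


def validate_label_table(labels: pd.DataFrame) -> pd.DataFrame:
    """Schema and invariant checks; returns the table unchanged."""
    for col in REQUIRED_COLUMNS:
        if col not in labels.columns:
            raise ValueError(f"label table missing required column {col!r}")
    dup = labels.duplicated(subset=["patient_id", "slide_id"])
    if dup.any():
        raise ValueError(f"duplicate (patient_id, slide_id) rows: {labels[dup].head()}")
    for task in task_columns(labels):
        per_patient = labels.groupby("patient_id")[task].nunique(dropna=True)
        bad = per_patient[per_patient > 1]
        if len(bad):
            raise ValueError(
                f"task {task!r}: label differs across slides of patients {list(bad.index)}"
            )
    return labels


def load_label_table(path: str) -> pd.DataFrame:
    return validate_label_table(pd.read_csv(path))


# -- splits -----------------------------------------------------------------


@dataclass
class SplitAssignment:
    assignment: dict[str, str]      # patient_id -> partition
    mode: str
    seed: int
    task: str

    def patients(self, partition: str) -> list[str]:
        return sorted(p for p, g in self.assignment.items() if g == partition)

    def partition_of(self, patient_id: str) -> Optional[str]:
        return self.assignment.get(patient_id)

    def check_no_leakage(self) -> None:
        sets = [set(self.patients(p)) for p in PARTITIONS]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise SplitInfeasibleError(
                        f"patients in two partitions: {sets[i] & sets[j]}"
                    )


def _allocate(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items to the given ratios."""
    total = sum(ratios)
    exact = [n * r / total for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    rem = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])
    for i in range(rem):
        base[order[i]] += 1
    return base


def _spread(counts: list[int]) -> list[int]:
    """Ensure every slot gets >= 1 by shifting from the largest slot."""
    counts = list(counts)
    while min(counts) == 0 and max(counts) > 1:
        counts[counts.index(0)] += 1
        counts[counts.index(max(counts))] -= 1
    return counts


def make_split(
    labels: pd.DataFrame,
    task: str,
    mode: str = "mixed",
    seed: int = 0,
    ratios: tuple[float, float, float] = (8, 1, 1),
    held_out_cohort: str = "B",
    train_val_ratio: tuple[float, float] = (9, 1),
) -> SplitAssignment:
    """Assign every labeled patient to train/validation/test.

    mixed
        Stratified random 8:1:1 split by patient, both classes guaranteed in
        every partition (infeasible stratifications raise).
    cohort_independent
        Test = every patient of the held-out cohort; the remaining cohort is
        split 9:1 into train and validation, stratified by class.

    Patients whose task label is missing are left out of the assignment and
    later excluded from that task's record store.
    """
    validate_label_table(labels)
    if task not in labels.columns:
        raise ValueError(f"unknown task {task!r}")
    per_patient = labels.dropna(subset=[task]).groupby("patient_id").agg(
        label=(task, "first"), cohort=("cohort", "first")
    )
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}

    def _assign_stratified(patients_by_class, parts, part_ratios):
        counts_by_class = {}
        for cls, pats in patients_by_class.items():
            if len(pats) < len(parts):
                raise SplitInfeasibleError(
                    f"task {task!r}: class {cls} has only {len(pats)} patients; "
                    f"cannot place one in each of {len(parts)} partitions"
                )
            counts_by_class[cls] = _spread(_allocate(len(pats), part_ratios))
        # per-class largest-remainder rounding can drift the global partition
        # sizes off the exact apportionment when remainders tie; correct by
        # shifting single patients while keeping every class in every partition
        total = sum(len(p) for p in patients_by_class.values())
        target = _allocate(total, part_ratios)
        cur = [sum(c[j] for c in counts_by_class.values()) for j in range(len(parts))]
        guard = 0
        while cur != target and guard < 100:
            guard += 1
            j_over = max(range(len(parts)), key=lambda j: cur[j] - target[j])
            j_under = min(range(len(parts)), key=lambda j: cur[j] - target[j])
            movable = [c for c in counts_by_class if counts_by_class[c][j_over] > 1]
            if not movable:
                break
            c = max(movable, key=lambda c: counts_by_class[c][j_over])
            counts_by_class[c][j_over] -= 1
            counts_by_class[c][j_under] += 1
            cur[j_over] -= 1
            cur[j_under] += 1
        for cls, pats in patients_by_class.items():
            pats = list(pats)
            rng.shuffle(pats)
            i = 0
            for part, k in zip(parts, counts_by_class[cls]):
                for p in pats[i : i + k]:
                    assignment[p] = part
                i += k

    by_class = {
        cls: list(grp.index) for cls, grp in per_patient.groupby("label", sort=True)
    }
    if len(by_class) < 2:
        raise SplitInfeasibleError(f"task {task!r} needs both classes labeled")

    if mode == "mixed":
        _assign_stratified(by_class, PARTITIONS, ratios)
    elif mode == "cohort_independent":
        held = per_patient[per_patient["cohort"] == held_out_cohort]
        rest = per_patient[per_patient["cohort"] != held_out_cohort]
        if held.empty or rest.empty:
            raise SplitInfeasibleError(
                f"cohort-independent split needs patients inside and outside "
                f"cohort {held_out_cohort!r}"
            )
        for cls in by_class:
            if (held["label"] == cls).sum() < 1 or (rest["label"] == cls).sum() < 2:
                raise SplitInfeasibleError(
                    f"class {cls} too small for cohort-independent split"
                )
        for p in held.index:
            assignment[p] = "test"
        rest_by_class = {
            cls: list(grp.index) for cls, grp in rest.groupby("label", sort=True)
        }
        _assign_stratified(rest_by_class, ("train", "validation"), train_val_ratio)
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    split = SplitAssignment(assignment, mode, seed, task)
    split.check_no_leakage()
    return split


# -- class weights ----------------------------------------------------------


@dataclass(frozen=True)
class ClassWeights:
    task: str
    weights: tuple[float, float]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def compute_class_weights(
    labels: pd.DataFrame,
    task: str,
    split: SplitAssignment,
    tile_counts: Optional[dict[str, int]] = None,
) -> ClassWeights:
    """w_c = N_train / (2 * N_train,c) over training tile sets.

    ``tile_counts`` maps slide_id to its kept tile-set count; without it each
    slide counts once (pure label composition).  Balanced classes give
    (1, 1); weights are invariant to the total count at fixed composition.
    """
    train_patients = set(split.patients("train"))
    rows = labels[labels["patient_id"].isin(train_patients)].dropna(subset=[task])
    n = np.zeros(2)
    for _, r in rows.iterrows():
        cnt = 1 if tile_counts is None else tile_counts.get(r["slide_id"], 0)
        n[int(r[task])] += cnt
    if np.any(n == 0):
        raise SplitInfeasibleError(
            f"task {task!r}: a class has no training tile sets (counts {n.tolist()})"
        )
    total = n.sum()
    w = total / (2.0 * n)
    return ClassWeights(task, (float(w[0]), float(w[1])))


# -- record store -----------------------------------------------------------

_MAGIC = b"PTRC"


def _pack_record(ts: TileSet, label: int, age: float, bmi: float) -> bytes:
    arrays = [np.ascontiguousarray(ts.images[m], dtype=np.uint8) for m in (10.0, 5.0, 2.5)]
    header = {
        "slide_id": ts.slide_id,
        "patient_id": ts.patient_id,
        "tile_set_id": ts.tile_set_id,
        "anchor_xy_level0": list(ts.anchor_xy_level0),
        "parent_cell_index": list(ts.parent_cell_index),
        "normalized": bool(ts.normalized),
        "label": int(label),
        "age": None if age is None or (isinstance(age, float) and np.isnan(age)) else float(age),
        "bmi": None if bmi is None or (isinstance(bmi, float) and np.isnan(bmi)) else float(bmi),
        "shapes": [list(a.shape) for a in arrays],
    }
    hb = json.dumps(header, sort_keys=True).encode()
    payload = b"".join(a.tobytes() for a in arrays)
    return _MAGIC + struct.pack("<II", len(hb), len(payload)) + hb + payload


def _unpack_records(blob: bytes) -> Iterator[dict]:
    off = 0
    while off < len(blob):
        if blob[off : off + 4] != _MAGIC:
            raise ManifestError(f"bad record magic at offset {off}")
        hlen, plen = struct.unpack_from("<II", blob, off + 4)
        off += 12
        header = json.loads(blob[off : off + hlen])
        off += hlen
        arrays = []
        for shape in header["shapes"]:
            n = int(np.prod(shape))
            arrays.append(
                np.frombuffer(blob, dtype=np.uint8, count=n, offset=off).reshape(shape)
            )
            off += n
        if off - 12 - hlen > len(blob):
            raise ManifestError("truncated record payload")
        rec = dict(header)
        rec["images"] = {10.0: arrays[0], 5.0: arrays[1], 2.5: arrays[2]}
        yield rec


class RecordWriter:
    """Sharded record sink for one partition."""

    def __init__(self, out_dir: Path, partition: str, shard_size: int = 128):
        self.out_dir = Path(out_dir)
        self.partition = partition
        self.shard_size = shard_size
        self.shards: list[dict] = []
        self._buf: list[bytes] = []
        self.n_per_class = {0: 0, 1: 0}

    def add(self, ts: TileSet, label: int, age=None, bmi=None) -> None:
        self._buf.append(_pack_record(ts, label, age, bmi))
        self.n_per_class[int(label)] += 1
        if len(self._buf) >= self.shard_size:
            self._flush()

    def _flush(self) -> None:
        if not self._buf:
            return
        name = f"records-{self.partition}-{len(self.shards):05d}.bin"
        blob = b"".join(self._buf)
        (self.out_dir / name).write_bytes(blob)
        self.shards.append(
            {
                "file": name,
                "sha256": hashlib.sha256(blob).hexdigest(),
                "n_records": len(self._buf),
            }
        )
        self._buf = []

    def close(self) -> dict:
        self._flush()
        return {
            "shards": self.shards,
            "n_records": int(sum(s["n_records"] for s in self.shards)),
            "n_per_class": {str(k): v for k, v in self.n_per_class.items()},
        }


def write_records(
    tile_sets: Iterable[TileSet],
    labels: pd.DataFrame,
    split: SplitAssignment,
    out_dir: str,
    shard_size: int = 128,
    config_fingerprint: str = "",
) -> str:
    """Serialize tile sets into per-partition shards; returns manifest path.

    Tile sets of patients without a label for the split's task are excluded
    and counted in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    task = split.task
    meta = labels.set_index("patient_id")
    label_of, age_of, bmi_of = {}, {}, {}
    for pid, grp in labels.groupby("patient_id"):
        v = grp[task].dropna()
        if len(v):
            label_of[pid] = int(v.iloc[0])
        age_of[pid] = grp["age"].iloc[0] if "age" in grp else None
        bmi_of[pid] = grp["bmi"].iloc[0] if "bmi" in grp else None

    writers = {p: RecordWriter(out, p, shard_size) for p in PARTITIONS}
    excluded: dict[str, int] = {}
    for ts in tile_sets:
        pid = ts.patient_id
        part = split.partition_of(pid)
        if pid not in label_of or part is None:
            excluded[pid] = excluded.get(pid, 0) + 1
            continue
        writers[part].add(ts, label_of[pid], age_of.get(pid), bmi_of.get(pid))

    manifest = {
        "task": task,
        "mode": split.mode,
        "seed": split.seed,
        "config_fingerprint": config_fingerprint,
        "partitions": {p: w.close() for p, w in writers.items()},
        "excluded_tile_sets": excluded,
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return str(mp)


def read_records(
    manifest_path: str,
    partition: str,
    shuffle_seed: Optional[int] = None,
    verify: bool = True,
) -> Iterator[dict]:
    """Stream records of one partition; order is reproducible given the seed."""
    mp = Path(manifest_path)
    try:
        manifest = json.loads(mp.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ManifestError(f"cannot read manifest {manifest_path!r}: {exc}") from exc
    if partition not in manifest["partitions"]:
        raise ManifestError(f"partition {partition!r} not in manifest")
    records: list[dict] = []
    for shard in manifest["partitions"][partition]["shards"]:
        blob = (mp.parent / shard["file"]).read_bytes()
        if verify and hashlib.sha256(blob).hexdigest() != shard["sha256"]:
            raise ManifestError(f"checksum mismatch in shard {shard['file']!r}")
        records.extend(_unpack_records(blob))
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(records))
        records = [records[i] for i in order]
    yield from records


# -- in-memory dataset ------------------------------------------------------


def _resize_tile(img: np.ndarray, px: int) -> np.ndarray:
    """Tile -> (3, px, px) float in [-0.5, 0.5]."""
    from skimage.transform import resize

    if img.shape[0] != px:
        img = resize(img, (px, px), order=1, preserve_range=True, anti_aliasing=True)
    return (img.astype(np.float64) / 255.0 - 0.5).transpose(2, 0, 1)


@dataclass
class TileSetDataset:
    """Materialized tile sets ready for the network: resized and centered."""

    x: dict[float, np.ndarray]              # magnification -> (N, 3, px, px)
    labels: np.ndarray                      # (N,) int
    clinical_raw: np.ndarray                # (N, 2) age, bmi with NaN for missing
    patient_ids: np.ndarray
    slide_ids: np.ndarray
    tile_set_ids: np.ndarray
    anchors: np.ndarray                     # (N, 2) level-0 10x anchors
    clinical: Optional[np.ndarray] = None   # (N, 4) imputed + flags, set later

    def __len__(self) -> int:
        return len(self.labels)

    def batch(self, idx: np.ndarray, clinical: bool = False) -> dict:
        out = {m: self.x[m][idx] for m in self.x}
        if clinical:
            if self.clinical is None:
                raise ValueError("clinical features not prepared; call impute_clinical")
            out["clinical"] = self.clinical[idx]
        return out

    @classmethod
    def from_records(
        cls,
        manifest_path: str,
        partition: str,
        input_px: int = 299,
        shuffle_seed: Optional[int] = None,
    ) -> "TileSetDataset":
        xs = {10.0: [], 5.0: [], 2.5: []}
        labels, clin, pids, sids, tids, anchors = [], [], [], [], [], []
        for rec in read_records(manifest_path, partition, shuffle_seed):
            for m in xs:
                xs[m].append(_resize_tile(rec["images"][m], input_px))
            labels.append(rec["label"])
            clin.append(
                [
                    np.nan if rec["age"] is None else rec["age"],
                    np.nan if rec["bmi"] is None else rec["bmi"],
                ]
            )
            pids.append(rec["patient_id"])
            sids.append(rec["slide_id"])
            tids.append(rec["tile_set_id"])
            anchors.append(rec["anchor_xy_level0"])
        n = len(labels)
        return cls(
            x={m: np.stack(v) if v else np.empty((0, 3, input_px, input_px)) for m, v in xs.items()},
            labels=np.asarray(labels, dtype=int),
            clinical_raw=np.asarray(clin, dtype=float).reshape(n, 2),
            patient_ids=np.asarray(pids, dtype=object),
            slide_ids=np.asarray(sids, dtype=object),
            tile_set_ids=np.asarray(tids, dtype=object),
            anchors=np.asarray(anchors, dtype=int).reshape(n, 2),
        )

    @classmethod
    def from_tile_sets(
        cls,
        tile_sets: Sequence[TileSet],
        label_of: Callable[[str], int],
        input_px: int = 299,
        clinical_of: Optional[Callable[[str], tuple[float, float]]] = None,
    ) -> "TileSetDataset":
        xs = {m: [] for m in (10.0, 5.0, 2.5)}
        labels, clin, pids, sids, tids, anchors = [], [], [], [], [], []
        for ts in tile_sets:
            for m in xs:
                xs[m].append(_resize_tile(ts.images[m], input_px))
            labels.append(label_of(ts.patient_id))
            clin.append(
                clinical_of(ts.patient_id) if clinical_of else (np.nan, np.nan)
            )
            pids.append(ts.patient_id)
            sids.append(ts.slide_id)
            tids.append(ts.tile_set_id)
            anchors.append(ts.anchor_xy_level0)
        n = len(labels)
        return cls(
            x={m: np.stack(v) if v else np.empty((0, 3, input_px, input_px)) for m, v in xs.items()},
            labels=np.asarray(labels, dtype=int),
            clinical_raw=np.asarray(clin, dtype=float).reshape(n, 2),
            patient_ids=np.asarray(pids, dtype=object),
            slide_ids=np.asarray(sids, dtype=object),
            tile_set_ids=np.asarray(tids, dtype=object),
            anchors=np.asarray(anchors, dtype=int).reshape(n, 2),
        )


def impute_clinical(train: TileSetDataset, *others: TileSetDataset) -> np.ndarray:
    """Median-impute age/BMI from the training set; append missingness flags.

    Fills ``.clinical`` on every dataset passed; returns the medians used.
    """
    med = np.nanmedian(train.clinical_raw, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    for ds in (train, *others):
        raw = ds.clinical_raw
        flags = np.isnan(raw).astype(float)
        filled = np.where(np.isnan(raw), med, raw)
        ds.clinical = np.concatenate([filled, flags], axis=1)
    return med
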