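"""Label tables, patient-level splits, class weights, and the record store."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from panoptes.cohort import (
    TileSetDataset,
    compute_class_weights,
    impute_clinical,
    load_label_table,
    make_split,
    read_records,
    validate_label_table,
    write_records,
)
from panoptes.errors import ManifestError, SplitInfeasibleError
from panoptes.tiling import TileSet


def label_frame(n_patients, n_pos=None, slides_per_patient=1, cohort_b=0):
    rows = []
    n_pos = n_patients // 2 if n_pos is None else n_pos
    # cohort B membership stratified across both classes
    b_set = set(range(cohort_b // 2)) | set(
        range(n_pos, n_pos + (cohort_b - cohort_b // 2))
    )
    for i in range(n_patients):
        for s in range(slides_per_patient):
            rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "slide_id": f"P{i:03d}-S{s}",
                    "cohort": "B" if i in b_set else "A",
                    "subtype": 1 if i < n_pos else 0,
                    "age": 60.0,
                    "bmi": 30.0,
                }
            )
    return pd.DataFrame(rows)


class TestLabelTable:
    def test_duplicate_slide_rejected(self):
        df = label_frame(4)
        with pytest.raises(ValueError, match="duplicate"):
            validate_label_table(pd.concat([df, df.iloc[:1]]))

    def test_inconsistent_patient_label_rejected(self):
        df = label_frame(4, slides_per_patient=2)
        df.loc[1, "subtype"] = 0
        with pytest.raises(ValueError, match="differs across slides"):
            validate_label_table(df)

    def test_csv_round_trip(self, tmp_path):
        df = label_frame(6)
        p = tmp_path / "labels.csv"
        df.to_csv(p, index=False)
        out = load_label_table(str(p))
        assert len(out) == 6


class TestMakeSplit:
    def test_mixed_100_patients_is_80_10_10(self):
        split = make_split(label_frame(100), "subtype", "mixed", seed=0)
        sizes = {p: len(split.patients(p)) for p in ("train", "validation", "test")}
        assert sizes == {"train": 80, "validation": 10, "test": 10}

    def test_multi_slide_patient_stays_together(self):
        labels = label_frame(20, slides_per_patient=3)
        split = make_split(labels, "subtype", "mixed", seed=1)
        for pid, grp in labels.groupby("patient_id"):
            parts = {split.partition_of(p) for p in grp["patient_id"]}
            assert len(parts) == 1

    def test_every_partition_has_both_classes(self):
        for seed in range(5):
            split = make_split(label_frame(20, n_pos=5), "subtype", "mixed", seed)
            labels = label_frame(20, n_pos=5).set_index("patient_id")["subtype"]
            for part in ("train", "validation", "test"):
                classes = {labels[p] for p in split.patients(part)}
                assert classes == {0, 1}

    def test_cohort_independent_ratios(self):
        # cohorts sized 90 (A) / 10 (B): test = all B, train:val = 81:9
        labels = label_frame(100, n_pos=50, cohort_b=10)
        split = make_split(labels, "subtype", "cohort_independent", seed=0)
        assert len(split.patients("test")) == 10
        assert len(split.patients("train")) == 81
        assert len(split.patients("validation")) == 9
        b_patients = set(labels[labels["cohort"] == "B"]["patient_id"])
        assert set(split.patients("test")) == b_patients

    def test_no_patient_leakage(self):
        split = make_split(label_frame(50), "subtype", "mixed", seed=3)
        parts = [set(split.patients(p)) for p in ("train", "validation", "test")]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_single_positive_is_infeasible(self):
        with pytest.raises(SplitInfeasibleError):
            make_split(label_frame(10, n_pos=1), "subtype", "mixed", seed=0)

    def test_deterministic_given_seed(self):
        a = make_split(label_frame(40), "subtype", "mixed", seed=9)
        b = make_split(label_frame(40), "subtype", "mixed", seed=9)
        assert a.assignment == b.assignment

    def test_unlabeled_patients_left_out(self):
        df = label_frame(20)
        df.loc[df["patient_id"] == "P000", "subtype"] = np.nan
        split = make_split(df, "subtype", "mixed", seed=0)
        assert split.partition_of("P000") is None


class TestClassWeights:
    def test_balanced_classes_unit_weights(self):
        labels = label_frame(20)
        split = make_split(labels, "subtype", "mixed", seed=0)
        w = compute_class_weights(labels, "subtype", split)
        assert w.weights == pytest.approx((1.0, 1.0))

    def test_75_25_composition(self):
        labels = label_frame(8, n_pos=2)
        split = type("S", (), {})()  # minimal stand-in: everyone trains
        from panoptes.cohort import SplitAssignment

        split = SplitAssignment(
            {f"P{i:03d}": "train" for i in range(8)}, "mixed", 0, "subtype"
        )
        w = compute_class_weights(labels, "subtype", split)
        assert w.weights[0] == pytest.approx(8 / (2 * 6))  # 0.667
        assert w.weights[1] == pytest.approx(8 / (2 * 2))  # 2.0

    def test_invariant_to_total_count(self):
        from panoptes.cohort import SplitAssignment

        for n in (8, 32):
            labels = label_frame(n, n_pos=n // 4)
            split = SplitAssignment(
                {f"P{i:03d}": "train" for i in range(n)}, "mixed", 0, "subtype"
            )
            w = compute_class_weights(labels, "subtype", split)
            assert w.weights == pytest.approx((2 / 3, 2.0))

    def test_tile_counts_weighting(self):
        from panoptes.cohort import SplitAssignment

        labels = label_frame(2, n_pos=1)
        split = SplitAssignment({"P000": "train", "P001": "train"}, "mixed", 0, "subtype")
        counts = {"P000-S0": 30, "P001-S0": 10}  # positive patient has 30 tiles
        w = compute_class_weights(labels, "subtype", split, counts)
        assert w.weights == pytest.approx((40 / 20, 40 / 60))


def _toy_tile_sets(n, patient_id="P000", slide_id="P000-S0", px=32):
    rng = np.random.default_rng(42)
    out = []
    for i in range(n):
        out.append(
            TileSet(
                slide_id=slide_id,
                patient_id=patient_id,
                anchor_xy_level0=(i * px, 0),
                images={m: rng.integers(0, 256, (px, px, 3), dtype=np.uint8)
                        for m in (10.0, 5.0, 2.5)},
                parent_cell_index=(0, i // 16),
            )
        )
    return out


class TestRecordStore:
    def _write(self, tmp_path, tile_sets, labels, split):
        return write_records(tile_sets, labels, split, str(tmp_path / "records"))

    def test_partition_counts(self, tmp_path):
        from panoptes.cohort import SplitAssignment

        labels = label_frame(1)
        split = SplitAssignment({"P000": "train"}, "mixed", 0, "subtype")
        manifest = self._write(tmp_path, _toy_tile_sets(64), labels, split)
        m = json.loads(Path(manifest).read_text())
        assert m["partitions"]["train"]["n_records"] == 64
        assert m["partitions"]["validation"]["n_records"] == 0
        assert m["partitions"]["test"]["n_records"] == 0

    def test_round_trip_lossless(self, tmp_path):
        from panoptes.cohort import SplitAssignment

        labels = label_frame(1)
        split = SplitAssignment({"P000": "train"}, "mixed", 0, "subtype")
        sets = _toy_tile_sets(5)
        manifest = self._write(tmp_path, sets, labels, split)
        recs = list(read_records(manifest, "train"))
        assert len(recs) == 5
        for ts, rec in zip(sets, recs):
            assert rec["tile_set_id"] == ts.tile_set_id
            assert rec["label"] == int(labels["subtype"].iloc[0])
            assert rec["age"] == 60.0
            for m in (10.0, 5.0, 2.5):
                np.testing.assert_array_equal(rec["images"][m], ts.images[m])

    def test_shuffled_read_reproducible(self, tmp_path):
        from panoptes.cohort import SplitAssignment

        labels = label_frame(1)
        split = SplitAssignment({"P000": "train"}, "mixed", 0, "subtype")
        manifest = self._write(tmp_path, _toy_tile_sets(40), labels, split)
        ids1 = [r["tile_set_id"] for r in read_records(manifest, "train", shuffle_seed=3)]
        ids2 = [r["tile_set_id"] for r in read_records(manifest, "train", shuffle_seed=3)]
        ids3 = [r["tile_set_id"] for r in read_records(manifest, "train", shuffle_seed=4)]
        assert ids1 == ids2
        assert ids1 != ids3
        # seeded-permutation oracle
        order = np.random.default_rng(3).permutation(40)
        plain = [r["tile_set_id"] for r in read_records(manifest, "train")]
        assert ids1 == [plain[i] for i in order]

    def test_missing_label_excluded_and_counted(self, tmp_path):
        from panoptes.cohort import SplitAssignment

        labels = label_frame(2)
        labels.loc[labels["patient_id"] == "P001", "subtype"] = np.nan
        split = SplitAssignment({"P000": "train"}, "mixed", 0, "subtype")
        sets = _toy_tile_sets(3) + _toy_tile_sets(2, "P001", "P001-S0")
        manifest = self._write(tmp_path, sets, labels, split)
        m = json.loads(Path(manifest).read_text())
        assert m["excluded_tile_sets"] == {"P001": 2}
        assert m["partitions"]["train"]["n_records"] == 3

    def test_checksum_corruption_detected(self, tmp_path):
        from panoptes.cohort import SplitAssignment

        labels = label_frame(1)
        split = SplitAssignment({"P000": "train"}, "mixed", 0, "subtype")
        manifest = self._write(tmp_path, _toy_tile_sets(4), labels, split)
        shard = next((tmp_path / "records").glob("records-train-*.bin"))
        blob = bytearray(shard.read_bytes())
        blob[100] ^= 0xFF
        shard.write_bytes(bytes(blob))
        with pytest.raises(ManifestError, match=shard.name):
            list(read_records(manifest, "train"))

    def test_manifest_counts_equal_streamed_counts(self, tmp_path):
        from panoptes.cohort import SplitAssignment

        labels = label_frame(2)
        split = SplitAssignment({"P000": "train", "P001": "test"}, "mixed", 0, "subtype")
        sets = _toy_tile_sets(20) + _toy_tile_sets(7, "P001", "P001-S0")
        manifest = self._write(tmp_path, sets, labels, split)
        m = json.loads(Path(manifest).read_text())
        for part in ("train", "test"):
            streamed = list(read_records(manifest, part))
            assert len(streamed) == m["partitions"][part]["n_records"]


class TestDataset:
    def test_from_records_and_clinical_imputation(self, tmp_path):
        from panoptes.cohort import SplitAssignment

        labels = label_frame(1)
        labels.loc[0, "bmi"] = np.nan
        split = SplitAssignment({"P000": "train"}, "mixed", 0, "subtype")
        manifest = write_records(
            _toy_tile_sets(6), labels, split, str(tmp_path / "r")
        )
        ds = TileSetDataset.from_records(manifest, "train", input_px=16)
        assert len(ds) == 6
        assert ds.x[10.0].shape == (6, 3, 16, 16)
        med = impute_clinical(ds)
        assert ds.clinical.shape == (6, 4)
        assert np.all(ds.clinical[:, 3] == 1.0)  # bmi missing flag set
        batch = ds.batch(np.array([0, 2]), clinical=True)
        assert batch[2.5].shape == (2, 3, 16, 16)
        assert batch["clinical"].shape == (2, 4)
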