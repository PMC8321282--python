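"""Balancing, segment-wise / patient-wise splits and fold plans."""

import numpy as np
import pytest

from ecgscreen import (
    ANOMALOUS,
    NORMAL,
    LeakageError,
    Segment,
    SegmentDataset,
    make_folds,
    split_patientwise,
    split_segmentwise,
    undersample_balance,
)
from ecgscreen.dataset import (
    DatasetError,
    DatasetSplit,
    choose_train_records,
    manifest_to_split,
    split_to_manifest,
    subsample_to_ratio,
)


def labeled_dataset(n_normal, n_anomalous, n_records=44, seg_len=4, seed=0):
    """Light-weight dataset with the requested class composition."""
    segments = []
    per_record = {}
    labels = [NORMAL] * n_normal + [ANOMALOUS] * n_anomalous
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    for i, label in enumerate(labels):
        rid = f"r{i % n_records:02d}"
        j = per_record.get(rid, 0)
        per_record[rid] = j + 1
        segments.append(
            Segment(record_id=rid, segment_index=j,
                    samples=np.zeros(seg_len), label=label)
        )
    return SegmentDataset(segments, seg_len=seg_len)


class TestUndersampleBalance:
    def test_reproduces_published_training_pool_composition(self):
        """2105 normal + 3175 anomalous, n=1465 -> 2930 pool, 640 normal left."""
        ds = labeled_dataset(2105, 3175)
        pool, leftover = undersample_balance(ds, 1465, seed=3)
        pool_labels = pool.labels
        assert len(pool) == 2930
        assert pool_labels.count(NORMAL) == pool_labels.count(ANOMALOUS) == 1465
        left_labels = leftover.labels
        assert left_labels.count(NORMAL) == 640
        assert left_labels.count(ANOMALOUS) == 3175 - 1465
        assert set(pool.ids) | set(leftover.ids) == set(ds.ids)
        assert not set(pool.ids) & set(leftover.ids)

    def test_equal_classes_at_minimum_leave_no_leftover(self):
        ds = labeled_dataset(10, 10)
        pool, leftover = undersample_balance(ds, 10, seed=0)
        assert len(leftover) == 0 and len(pool) == 20

    def test_same_seed_gives_identical_pools(self):
        ds = labeled_dataset(50, 80)
        a, _ = undersample_balance(ds, 30, seed=9)
        b, _ = undersample_balance(ds, 30, seed=9)
        assert a.ids == b.ids

    def test_too_small_class_reports_available_count(self):
        ds = labeled_dataset(5, 50)
        with pytest.raises(DatasetError, match="only 5"):
            undersample_balance(ds, 10)

    def test_subsample_to_published_test_ratio(self):
        ds = labeled_dataset(640, 1710)
        sub = subsample_to_ratio(ds, 640, 426, seed=0)
        assert sub.labels.count(NORMAL) == 640
        assert sub.labels.count(ANOMALOUS) == 426


class TestSplitSegmentwise:
    def test_seventy_thirty_split_sizes(self):
        ds = labeled_dataset(1465, 1465)
        split = split_segmentwise(ds, 0.7, 0.3, seed=1)
        assert abs(len(split.train_ids) - 2051) <= 1
        assert abs(len(split.validation_ids) - 879) <= 1
        assert len(split.train_ids) + len(split.validation_ids) == 2930

    def test_stratification_preserves_class_ratio(self):
        ds = labeled_dataset(200, 100)
        split = split_segmentwise(ds, 0.7, 0.3, seed=5)
        by_id = ds.by_id()
        for part in (split.train_ids, split.validation_ids):
            labels = [by_id[i].label for i in part]
            # pool ratio is 2:1; each part matches within one member
            assert abs(labels.count(NORMAL) - 2 * labels.count(ANOMALOUS)) <= 2

    def test_full_train_fraction_leaves_empty_validation(self):
        ds = labeled_dataset(10, 10)
        split = split_segmentwise(ds, 1.0, 0.0, seed=0)
        assert split.validation_ids == [] and len(split.train_ids) == 20

    def test_parts_are_disjoint_and_cover_pool(self):
        ds = labeled_dataset(37, 23)
        split = split_segmentwise(ds, 0.5, 0.25, seed=2)
        parts = [set(split.train_ids), set(split.validation_ids), set(split.test_ids)]
        assert sum(len(p) for p in parts) == 60
        assert parts[0] | parts[1] | parts[2] == set(ds.ids)


class TestSplitPatientwise:
    def test_no_test_record_segment_in_train(self):
        ds = labeled_dataset(20, 20, n_records=4)
        split = split_patientwise(ds, ["r00", "r01"])
        assert all(rid in ("r00", "r01") for rid, _ in split.train_ids)
        assert all(rid in ("r02", "r03") for rid, _ in split.test_ids)

    def test_28_of_44_records_leaves_16_in_test(self):
        ds = labeled_dataset(300, 300, n_records=44)
        chosen = choose_train_records(ds, 28, seed=7)
        split = split_patientwise(ds, chosen)
        assert len({r for r, _ in split.test_ids}) == 16
        assert split.audit_leakage() == set()

    def test_moving_one_record_moves_exactly_its_segments(self):
        ds = labeled_dataset(30, 30, n_records=5)
        counts = ds.source_map()
        a = split_patientwise(ds, ["r00", "r01", "r02"])
        b = split_patientwise(ds, ["r00", "r01"])
        assert len(a.train_ids) - len(b.train_ids) == counts["r02"]
        assert len(b.test_ids) - len(a.test_ids) == counts["r02"]

    def test_unknown_record_id_rejected(self):
        ds = labeled_dataset(10, 10, n_records=3)
        with pytest.raises(DatasetError, match="unknown record"):
            split_patientwise(ds, ["r99"])

    def test_leakage_audit_raises_in_patientwise_mode(self):
        split = DatasetSplit(
            train_ids=[("r1", 0)], test_ids=[("r1", 1)], mode="patientwise"
        )
        with pytest.raises(LeakageError):
            split.audit_leakage()


class TestMakeFolds:
    def test_hundred_ids_ten_equal_folds(self):
        ids = [("r", i) for i in range(100)]
        plan = make_folds(ids, k=10, seed=0)
        sizes = [len(plan.fold_ids(f)) for f in range(10)]
        assert sizes == [10] * 10

    def test_folds_partition_the_ids(self):
        ds = labeled_dataset(33, 44)
        plan = make_folds(ds.ids, k=10, seed=1,
                          stratify_labels=dict(zip(ds.ids, ds.labels)))
        all_ids = [i for f in range(10) for i in plan.fold_ids(f)]
        assert sorted(all_ids) == sorted(ds.ids)
        assert max(len(plan.fold_ids(f)) for f in range(10)) - min(
            len(plan.fold_ids(f)) for f in range(10)
        ) <= 1

    def test_each_id_validated_exactly_once(self):
        ids = [("r", i) for i in range(25)]
        plan = make_folds(ids, k=5, seed=0)
        validated = []
        for train, val in plan.rounds():
            assert not set(train) & set(val)
            assert sorted(train + val) == sorted(ids)
            validated.extend(val)
        assert sorted(validated) == sorted(ids)

    def test_k_larger_than_pool_rejected(self):
        with pytest.raises(DatasetError, match="exceeds"):
            make_folds([("r", 0)], k=2)


class TestManifest:
    def test_round_trip_and_byte_identical_determinism(self, tmp_path):
        ds = labeled_dataset(40, 40, n_records=8)
        paths = []
        for run in range(2):
            split = split_segmentwise(ds, 0.6, 0.2, seed=11)
            df = split_to_manifest(split, ds)
            p = tmp_path / f"manifest_{run}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        back = manifest_to_split(
            __import__("pandas").read_csv(paths[0])
        )
        split = split_segmentwise(ds, 0.6, 0.2, seed=11)
        assert back.train_ids == sorted(split.train_ids)
        assert back.test_ids == sorted(split.test_ids)
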