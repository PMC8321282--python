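"""Balanced pools, segment-wise and patient-wise splits, k-fold plans.

Two experimental designs are supported:

* **segment-wise** — segments from any recording may land in train,
  validation or test (the common holdout practice, prone to identity
  leakage between windows of the same patient);
* **patient-wise** — all segments of a recording stay on one side, so the
  test set contains only patients the model has never seen.

Class imbalance is handled by undersampling only: the majority class is
subsampled to the requested per-class size and the surplus flows to the
test pool.  All sampling is seeded and tie-broken by the lexicographic
``(record_id, segment_index)`` order so identical inputs give byte-identical
manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmenter import ANOMALOUS, NORMAL, SegmentDataset

SegmentId = tuple[str, int]


class DatasetError(Exception):
    pass


class LeakageError(DatasetError):
    """A patient-wise split shares a recording between train and test."""


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test id sets over a segment dataset."""

    train_ids: list[SegmentId]
    validation_ids: list[SegmentId] = field(default_factory=list)
    test_ids: list[SegmentId] = field(default_factory=list)
    mode: str = "segmentwise"
    seed: int | None = None

    def __post_init__(self):
        parts = [set(self.train_ids), set(self.validation_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise DatasetError("train/validation/test id sets are not disjoint")

    def audit_leakage(self) -> set[str]:
        """Record ids shared between (train ∪ validation) and test.

        Must be empty in patient-wise mode; raises :class:`LeakageError`
        there if not.
        """
        trainval = {rid for rid, _ in self.train_ids} | {
            rid for rid, _ in self.validation_ids
        }
        test = {rid for rid, _ in self.test_ids}
        shared = trainval & test
        if self.mode == "patientwise" and shared:
            raise LeakageError(f"patient leakage between train and test: {sorted(shared)}")
        return shared


@dataclass
class FoldPlan:
    """Assignment of ids to k cross-validation folds (sizes differ by <= 1)."""

    k: int
    assignment: dict[SegmentId, int]
    seed: int | None = None

    def fold_ids(self, fold: int) -> list[SegmentId]:
        return sorted(i for i, f in self.assignment.items() if f == fold)

    def rounds(self):
        """Yield (train_ids, validation_ids) per fold round.

        Each id is validated exactly once across the k rounds.
        """
        for fold in range(self.k):
            val = self.fold_ids(fold)
            train = sorted(i for i, f in self.assignment.items() if f != fold)
            yield train, val


def _sorted_ids(ds: SegmentDataset, label: str) -> list[SegmentId]:
    return sorted(
        (s.record_id, s.segment_index) for s in ds.segments if s.label == label
    )


def undersample_balance(
    ds: SegmentDataset, n_per_class: int, seed: int = 0
) -> tuple[SegmentDataset, SegmentDataset]:
    """Uniform, seeded, without-replacement draw of n per class.

    Returns ``(balanced_pool, leftover_pool)``; the leftover is the exact
    complement and typically feeds the test set.
    """
    rng = np.random.default_rng(seed)
    chosen: list[SegmentId] = []
    leftover: list[SegmentId] = []
    for label in (NORMAL, ANOMALOUS):
        ids = _sorted_ids(ds, label)
        if len(ids) < n_per_class:
            raise DatasetError(
                f"class {label!r} has only {len(ids)} segments, need {n_per_class}"
            )
        pick = rng.choice(len(ids), size=n_per_class, replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[pick] = True
        chosen.extend(ids[i] for i in np.flatnonzero(mask))
        leftover.extend(ids[i] for i in np.flatnonzero(~mask))
    return ds.subset(sorted(chosen)), ds.subset(sorted(leftover))


def subsample_to_ratio(
    ds: SegmentDataset, n_normal: int, n_anomalous: int, seed: int = 0
) -> SegmentDataset:
    """Seeded draw of a fixed per-class composition (e.g. a 60/40 test set)."""
    rng = np.random.default_rng(seed)
    out: list[SegmentId] = []
    for label, n in ((NORMAL, n_normal), (ANOMALOUS, n_anomalous)):
        ids = _sorted_ids(ds, label)
        if len(ids) < n:
            raise DatasetError(f"class {label!r} has only {len(ids)} segments, need {n}")
        pick = sorted(rng.choice(len(ids), size=n, replace=False))
        out.extend(ids[i] for i in pick)
    return ds.subset(sorted(out))


def split_segmentwise(
    ds: SegmentDataset,
    train_fraction: float = 0.7,
    val_fraction: float = 0.3,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified random split of segments into train/validation(/test).

    Per-class counts are within 1 of the exact fractions; whatever the two
    fractions leave over goes to test.
    """
    if not (0 < train_fraction <= 1) or not (0 <= val_fraction < 1):
        raise DatasetError("fractions must satisfy 0 < train <= 1, 0 <= val < 1")
    if train_fraction + val_fraction > 1 + 1e-9:
        raise DatasetError("train_fraction + val_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    train: list[SegmentId] = []
    val: list[SegmentId] = []
    test: list[SegmentId] = []
    for label in (NORMAL, ANOMALOUS):
        ids = _sorted_ids(ds, label)
        if not ids:
            raise DatasetError(f"class {label!r} is empty")
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_val = min(int(round(val_fraction * len(ids))), len(ids) - n_train)
        train.extend(ids[i] for i in perm[:n_train])
        val.extend(ids[i] for i in perm[n_train : n_train + n_val])
        test.extend(ids[i] for i in perm[n_train + n_val :])
    return DatasetSplit(
        train_ids=sorted(train),
        validation_ids=sorted(val),
        test_ids=sorted(test),
        mode="segmentwise",
        seed=seed,
    )


def split_patientwise(ds: SegmentDataset, train_record_ids) -> DatasetSplit:
    """Record-disjoint split: all segments of a train record stay in train.

    ``train_record_ids`` must be a non-empty proper subset of the dataset's
    records; every segment of any other record goes to test.
    """
    all_records = set(ds.record_ids)
    train_records = set(train_record_ids)
    unknown = train_records - all_records
    if unknown:
        raise DatasetError(f"unknown record id(s): {sorted(unknown)}")
    if not train_records or train_records == all_records:
        raise DatasetError("train records must be a non-empty proper subset")
    train = sorted(
        (s.record_id, s.segment_index)
        for s in ds.segments
        if s.record_id in train_records
    )
    test = sorted(
        (s.record_id, s.segment_index)
        for s in ds.segments
        if s.record_id not in train_records
    )
    split = DatasetSplit(train_ids=train, test_ids=test, mode="patientwise")
    split.audit_leakage()
    return split


def choose_train_records(ds: SegmentDataset, n_train: int, seed: int = 0) -> list[str]:
    """Seeded random choice of n training records (when no list is supplied)."""
    records = sorted(set(ds.record_ids))
    if not (0 < n_train < len(records)):
        raise DatasetError(
            f"n_train must be in (0, {len(records)}) for {len(records)} records"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(records), size=n_train, replace=False)
    return sorted(records[i] for i in pick)


def make_folds(
    ids, k: int = 10, seed: int = 0, stratify_labels: dict | None = None
) -> FoldPlan:
    """Partition ids into k folds of near-equal size, stratified by label.

    Within each label group ids are shuffled (seeded) and dealt round-robin;
    fold sizes over the whole plan differ by at most 1.
    """
    ids = sorted(ids)
    if k < 2:
        raise DatasetError("k must be >= 2")
    if k > len(ids):
        raise DatasetError(f"k={k} exceeds the {len(ids)} available ids")
    rng = np.random.default_rng(seed)
    if stratify_labels is None:
        groups = {None: ids}
    else:
        groups = {}
        for i in ids:
            groups.setdefault(stratify_labels[i], []).append(i)
    assignment: dict[SegmentId, int] = {}
    fold_sizes = np.zeros(k, dtype=int)
    for label in sorted(groups, key=str):
        members = groups[label]
        perm = rng.permutation(len(members))
        # Deal each id into the currently smallest fold (stable argmin), which
        # keeps global fold sizes within 1 and spreads every label group.
        for m in perm:
            fold = int(np.argmin(fold_sizes))
            assignment[members[m]] = fold
            fold_sizes[fold] += 1
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def split_to_manifest(
    split: DatasetSplit,
    ds: SegmentDataset,
    fold_plan: FoldPlan | None = None,
) -> pd.DataFrame:
    """Tabular manifest: record_id, segment_index, label, partition, fold."""
    by_id = ds.by_id()
    rows = []
    for partition, ids in (
        ("train", split.train_ids),
        ("validation", split.validation_ids),
        ("test", split.test_ids),
    ):
        for sid in ids:
            rows.append(
                {
                    "record_id": sid[0],
                    "segment_index": sid[1],
                    "label": by_id[sid].label,
                    "partition": partition,
                    "fold": (
                        fold_plan.assignment.get(sid, -1) if fold_plan is not None else -1
                    ),
                }
            )
    df = pd.DataFrame(
        rows, columns=["record_id", "segment_index", "label", "partition", "fold"]
    )
    return df.sort_values(["partition", "record_id", "segment_index"]).reset_index(
        drop=True
    )


def manifest_to_split(df: pd.DataFrame) -> DatasetSplit:
    """Rebuild a :class:`DatasetSplit` from a manifest frame or CSV load."""
    def ids(part):
        sel = df[df["partition"] == part]
        return sorted(
            (str(r), int(s)) for r, s in zip(sel["record_id"], sel["segment_index"])
        )

    return DatasetSplit(
        train_ids=ids("train"),
        validation_ids=ids("validation"),
        test_ids=ids("test"),
    )
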