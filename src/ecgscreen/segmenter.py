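"""Fragmenting single-lead recordings into fixed windows and labeling them.

A 30-minute recording at 360 Hz is cut into contiguous, non-overlapping
15-second windows of 5400 samples each.  Every beat/rhythm annotation falls
into exactly one window (half-open ``[start, end)`` in 0-based sample
coordinates), and the window inherits an **anomalous** label as soon as a
single event in it carries an anomalous symbol; a window whose events are
all normal is labeled **normal**.  Rhythm-change and signal-quality events
count as anomalous just like beat-level anomalies — the screening question
is "does anything here need a cardiologist's eye", not "which arrhythmia".
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import AnnotationTrack, Recording

logger = logging.getLogger(__name__)

NORMAL = "normal"
ANOMALOUS = "anomalous"

#: Default normal beat symbol.
DEFAULT_NORMAL_SYMBOLS = frozenset({"N"})

#: The 21 anomalous classes: beat anomalies, rhythm changes and
#: signal-quality events, screened with no distinction.  Keys are the
#: MIT-BIH annotation symbols, values the human-readable class names.
ANOMALOUS_CLASSES = {
    "L": "Left bundle branch block beat",
    "R": "Right bundle branch block beat",
    "A": "Atrial premature beat",
    "a": "Aberrated atrial premature beat",
    "J": "Nodal (junctional) premature beat",
    "S": "Supraventricular premature beat",
    "V": "Premature ventricular contraction",
    "F": "Fusion of ventricular and normal beat",
    "!": "Ventricular flutter wave",
    "e": "Atrial escape beat",
    "j": "Nodal (junctional) escape beat",
    "E": "Ventricular escape beat",
    "/": "Paced beat",
    "f": "Fusion of paced and normal beat",
    "x": "Non-conducted P-wave (blocked APB)",
    "Q": "Unclassifiable beat",
    "|": "Isolated QRS-like artifact",
    "~": "Change in signal quality",
    "+": "Rhythm change",
    "[": "Start of ventricular flutter/fibrillation",
    "]": "End of ventricular flutter/fibrillation",
}

DEFAULT_ANOMALOUS_SYMBOLS = frozenset(ANOMALOUS_CLASSES)


class SegmenterError(Exception):
    pass


class UnknownSymbol(SegmenterError):
    """An annotation symbol not classified by the symbol map.

    Unknown symbols are never silently treated as normal.
    """


@dataclass(frozen=True)
class SymbolMap:
    """Partition of annotation symbols into normal and anomalous classes."""

    normal_symbols: frozenset = DEFAULT_NORMAL_SYMBOLS
    anomalous_symbols: frozenset = DEFAULT_ANOMALOUS_SYMBOLS

    def __post_init__(self):
        object.__setattr__(self, "normal_symbols", frozenset(self.normal_symbols))
        object.__setattr__(self, "anomalous_symbols", frozenset(self.anomalous_symbols))
        if not self.normal_symbols or not self.anomalous_symbols:
            raise SegmenterError("both symbol sets must be non-empty")
        overlap = self.normal_symbols & self.anomalous_symbols
        if overlap:
            raise SegmenterError(f"symbols classified both ways: {sorted(overlap)}")


@dataclass
class Segment:
    """One fixed-length window of single-lead signal with its binary label.

    The window covers samples ``[segment_index * seg_len,
    (segment_index + 1) * seg_len)`` of its source recording.
    ``symbols_present`` is the multiset of annotation symbols that fell in
    the window; it is retained so multi-anomaly segments stay inspectable
    even though the label is binary.
    """

    record_id: str
    segment_index: int
    samples: np.ndarray
    label: str | None = None
    symbols_present: Counter = field(default_factory=Counter)
    annotated: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples).ravel()
        if self.segment_index < 0:
            raise SegmenterError("segment_index must be non-negative")

    @property
    def seg_len(self) -> int:
        return self.samples.shape[0]


@dataclass
class SegmentDataset:
    """A collection of labeled segments with per-record provenance."""

    segments: list[Segment]
    seg_len: int
    lead: str = "MLII"

    def __post_init__(self):
        seen = set()
        for seg in self.segments:
            key = (seg.record_id, seg.segment_index)
            if key in seen:
                raise SegmenterError(f"duplicate segment {key}")
            seen.add(key)
            if seg.seg_len != self.seg_len:
                raise SegmenterError(
                    f"segment {key} has length {seg.seg_len}, expected {self.seg_len}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def ids(self) -> list[tuple[str, int]]:
        return [(s.record_id, s.segment_index) for s in self.segments]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    @property
    def record_ids(self) -> list[str]:
        """Distinct source record ids, in first-seen order."""
        return list(dict.fromkeys(s.record_id for s in self.segments))

    def source_map(self) -> dict[str, int]:
        """Per-record segment counts."""
        counts: dict[str, int] = {}
        for s in self.segments:
            counts[s.record_id] = counts.get(s.record_id, 0) + 1
        return counts

    def by_id(self) -> dict[tuple[str, int], Segment]:
        return {(s.record_id, s.segment_index): s for s in self.segments}

    def subset(self, ids) -> "SegmentDataset":
        index = self.by_id()
        return SegmentDataset([index[i] for i in ids], seg_len=self.seg_len, lead=self.lead)

    def signal_matrix(self) -> np.ndarray:
        """(n_segments, seg_len) stacked raw signals."""
        if not self.segments:
            return np.empty((0, self.seg_len))
        return np.stack([s.samples for s in self.segments])

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: columns ``<lead>_0 .. <lead>_{seg_len-1}``, ``Type``.

        ``Type`` is ``N`` for normal and ``A`` for anomalous.
        """
        cols = [f"{self.lead}_{i}" for i in range(self.seg_len)]
        mat = self.signal_matrix()
        df = pd.DataFrame(mat, columns=cols)
        df["Type"] = ["A" if s.label == ANOMALOUS else "N" for s in self.segments]
        df.insert(0, "record_id", [s.record_id for s in self.segments])
        df.insert(1, "segment_index", [s.segment_index for s in self.segments])
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SegmentDataset":
        df = pd.read_csv(path)
        lead_cols = [c for c in df.columns if "_" in c and c.rsplit("_", 1)[1].isdigit()]
        lead = lead_cols[0].rsplit("_", 1)[0]
        lead_cols = sorted(lead_cols, key=lambda c: int(c.rsplit("_", 1)[1]))
        has_ids = "record_id" in df.columns
        segments = []
        for i, row in df.iterrows():
            segments.append(
                Segment(
                    record_id=str(row["record_id"]) if has_ids else "rec",
                    segment_index=int(row["segment_index"]) if has_ids else int(i),
                    samples=row[lead_cols].to_numpy(dtype=np.float64),
                    label=ANOMALOUS if str(row["Type"]).strip() == "A" else NORMAL,
                )
            )
        return cls(segments, seg_len=len(lead_cols), lead=lead)


def segment_length(window_seconds: float, sampling_rate: float) -> int:
    """Samples per window; must come out to a positive integer (15 s @ 360 Hz -> 5400)."""
    seg_len = window_seconds * sampling_rate
    if seg_len <= 0 or abs(seg_len - round(seg_len)) > 1e-9:
        raise SegmenterError(
            f"window of {window_seconds} s at {sampling_rate} Hz is not a positive "
            f"integer number of samples ({seg_len})"
        )
    return int(round(seg_len))


def fragment(rec: Recording, window_seconds: float = 15.0) -> list[Segment]:
    """Cut a single-lead recording into unlabeled fixed-length windows.

    Windows are contiguous, non-overlapping and left-aligned; a trailing
    partial window is dropped, so the count is ``floor(n / seg_len)``.
    """
    if len(rec.lead_names) != 1:
        raise SegmenterError(
            f"fragment expects a single-lead recording, got leads {rec.lead_names}"
        )
    seg_len = segment_length(window_seconds, rec.sampling_rate)
    x = rec.samples[:, 0]
    n_windows = len(x) // seg_len
    return [
        Segment(
            record_id=rec.record_id,
            segment_index=i,
            samples=x[i * seg_len : (i + 1) * seg_len],
        )
        for i in range(n_windows)
    ]


def assign_annotations(segments: list[Segment], track: AnnotationTrack) -> list[Segment]:
    """Fill each segment's ``symbols_present`` from the annotation track.

    An event at sample ``s`` belongs to window ``floor(s / seg_len)``; events
    beyond the covered span (including any dropped trailing partial window)
    are dropped with a warning.  Modifies and returns ``segments``.
    """
    if not segments:
        return segments
    rid = segments[0].record_id
    if track.record_id != rid:
        raise SegmenterError(
            f"annotation track {track.record_id!r} does not match segments {rid!r}"
        )
    seg_len = segments[0].seg_len
    by_index = {s.segment_index: s for s in segments}
    dropped = 0
    for idx, sym, _ in track.events:
        w = idx // seg_len
        if w in by_index:
            by_index[w].symbols_present[sym] += 1
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{rid}: dropped {dropped} annotation event(s) beyond the segmented span",
            stacklevel=2,
        )
    for s in segments:
        s.annotated = sum(s.symbols_present.values()) > 0
    return segments


def label_segment(symbols_present, symbol_map: SymbolMap = SymbolMap()) -> str:
    """Binary label from the window's annotation symbols.

    Anomalous iff at least one symbol is in the anomalous set; normal iff
    all symbols are normal.  A symbol in neither set raises
    :class:`UnknownSymbol` — never silently normal.  An empty window labels
    normal (the caller tracks ``annotated=False``).
    """
    symbols = set(symbols_present)
    unknown = symbols - symbol_map.normal_symbols - symbol_map.anomalous_symbols
    if unknown:
        raise UnknownSymbol(f"unclassified annotation symbol(s): {sorted(unknown)}")
    if symbols & symbol_map.anomalous_symbols:
        return ANOMALOUS
    return NORMAL


def build_segment_dataset(
    rec: Recording,
    track: AnnotationTrack,
    symbol_map: SymbolMap = SymbolMap(),
    window_seconds: float = 15.0,
    include_unannotated: bool = True,
) -> SegmentDataset:
    """fragment -> assign_annotations -> label_segment, as one dataset.

    Unannotated windows are labeled normal, flagged ``annotated=False`` and
    counted in the log; set ``include_unannotated=False`` to exclude them.
    """
    segments = fragment(rec, window_seconds)
    assign_annotations(segments, track)
    n_unannotated = 0
    kept = []
    for seg in segments:
        seg.label = label_segment(seg.symbols_present, symbol_map)
        if not seg.annotated:
            n_unannotated += 1
            if not include_unannotated:
                continue
        kept.append(seg)
    if n_unannotated:
        logger.warning(
            "%s: %d window(s) carried no annotations (labeled normal%s)",
            rec.record_id,
            n_unannotated,
            "" if include_unannotated else ", excluded",
        )
    seg_len = segment_length(window_seconds, rec.sampling_rate)
    return SegmentDataset(kept, seg_len=seg_len, lead=rec.lead_names[0])
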