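"""Reading and writing MIT-BIH-style sample and annotation tables.

The on-disk dialect mirrors the Kaggle CSV export of the MIT-BIH Arrhythmia
Database: a *signal table* with one header line naming the leads and one row
of integer ADC values per sample, and an *annotation table* with one row per
expert-annotated sample (timestamp text, sample index, symbol).  Signals are
quantised with 11-bit resolution over a ±5 mV range, so ADC values live in
[0, 2047] with 1024 corresponding to 0 V.

Values are kept as raw ADC integers internally; conversion to millivolts is
explicit and opt-in (:func:`adc_to_millivolts`), so the signal fed downstream
is exactly what was recorded.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

ADC_ZERO = 1024
ADC_MAX = 2047
ADC_MV_RANGE = 10.0  # full-scale span of the ±5 mV quantiser
ADC_LEVELS = 2048
DEFAULT_SAMPLING_RATE = 360.0


class SignalIOError(Exception):
    """Base error for table parsing/validation failures."""


class LeadUnavailable(SignalIOError):
    """Requested lead is not present in the recording.

    Callers use this to exclude recordings, mirroring the handling of the
    four database records that carry only V1/V5 and no MLII.
    """


@dataclass
class Recording:
    """A multi-lead sampled signal in ADC units (or, explicitly, mV).

    Attributes
    ----------
    record_id : str
        Identifier of the source recording (e.g. ``"100"``).
    sampling_rate : float
        Samples per second; the database standard is 360 Hz.
    lead_names : list of str
        Ordered, unique lead names, one per signal column.
    samples : ndarray, shape (n_samples, n_leads)
        Integer ADC values in ``[0, 2047]`` when ``unit_mode == "adc"``,
        floats in millivolts when ``unit_mode == "mv"``.
    unit_mode : {"adc", "mv"}
    """

    record_id: str
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    lead_names: list[str] = field(default_factory=list)
    samples: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.int64))
    unit_mode: str = "adc"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise SignalIOError("samples must be a 2-D (n_samples, n_leads) array")
        if self.sampling_rate <= 0:
            raise SignalIOError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise SignalIOError(f"lead names must be unique, got {self.lead_names}")
        if self.samples.size and self.samples.shape[1] != len(self.lead_names):
            raise SignalIOError(
                f"{len(self.lead_names)} lead names but {self.samples.shape[1]} signal columns"
            )
        if self.unit_mode not in ("adc", "mv"):
            raise SignalIOError(f"unit_mode must be 'adc' or 'mv', got {self.unit_mode!r}")
        if self.unit_mode == "adc" and self.samples.size:
            if not np.issubdtype(self.samples.dtype, np.integer):
                raise SignalIOError("ADC-mode samples must be integers")
            lo, hi = self.samples.min(), self.samples.max()
            if lo < 0 or hi > ADC_MAX:
                raise SignalIOError(
                    f"ADC values must lie in [0, {ADC_MAX}]; found range [{lo}, {hi}]"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        """Return the 1-D signal of one lead."""
        if name not in self.lead_names:
            raise LeadUnavailable(
                f"record {self.record_id!r} has leads {self.lead_names}, not {name!r}"
            )
        return self.samples[:, self.lead_names.index(name)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.record_id == other.record_id
            and self.sampling_rate == other.sampling_rate
            and self.lead_names == other.lead_names
            and self.unit_mode == other.unit_mode
            and self.samples.shape == other.samples.shape
            and bool(np.array_equal(self.samples, other.samples))
        )


@dataclass
class AnnotationTrack:
    """Ordered (sample_index, symbol) beat/rhythm events for one recording.

    ``time_text`` is carried as an opaque string and never parsed for logic;
    ``sample_index`` is the single source of truth for event position.
    """

    record_id: str
    events: list[tuple[int, str, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for ev in self.events:
            idx, sym = int(ev[0]), str(ev[1])
            time_text = ev[2] if len(ev) > 2 else None
            if idx < 0:
                raise SignalIOError(f"annotation sample index must be >= 0, got {idx}")
            if not sym:
                raise SignalIOError("annotation symbol must be a non-empty string")
            norm.append((idx, sym, time_text))
        self.events = norm

    @property
    def sample_indices(self) -> np.ndarray:
        return np.array([e[0] for e in self.events], dtype=np.int64)

    @property
    def symbols(self) -> list[str]:
        return [e[1] for e in self.events]

    def __len__(self) -> int:
        return len(self.events)


def adc_to_millivolts(value):
    """Convert ADC units to millivolts: ``(value - 1024) * 10 / 2048``.

    The mapping is affine and strictly increasing; 1024 is exactly 0 V and
    the rails 0 / 2047 map to -5.0 / +4.99512 mV.  Accepts scalars or arrays.
    """
    arr = np.asarray(value)
    if arr.size and (arr.min() < 0 or arr.max() > ADC_MAX):
        raise SignalIOError(f"ADC values must lie in [0, {ADC_MAX}]")
    mv = (arr.astype(np.float64) - ADC_ZERO) * ADC_MV_RANGE / ADC_LEVELS
    return float(mv) if np.isscalar(value) or arr.ndim == 0 else mv


def millivolts_to_adc(mv):
    """Inverse of :func:`adc_to_millivolts`, rounded and clipped to [0, 2047]."""
    arr = np.asarray(mv, dtype=np.float64)
    adc = np.rint(arr * ADC_LEVELS / ADC_MV_RANGE + ADC_ZERO).astype(np.int64)
    return np.clip(adc, 0, ADC_MAX)


def select_lead(rec: Recording, lead: str) -> Recording:
    """Project a recording onto a single lead, preserving provenance.

    Raises :class:`LeadUnavailable` when the lead is absent — the caller's
    cue to exclude the recording (MLII is the lead used throughout).
    """
    column = rec.lead(lead)
    return replace(rec, lead_names=[lead], samples=column.reshape(-1, 1))


def _sniff_delimiter(header_line: str) -> str:
    return "," if "," in header_line else None  # None => any-whitespace split


def _split(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.split()
    return next(csv.reader([line], delimiter=delim))


# Optional leading index column in Kaggle exports (named or unnamed '' header).
_INDEX_HEADERS = {"", "sample", "sample #", "index", "#"}


def read_signal_table(path, sampling_rate: float = DEFAULT_SAMPLING_RATE) -> Recording:
    """Read a sample table: one header row naming leads, integer ADC rows.

    Comma-separated and whitespace-separated variants are both accepted
    (delimiter auto-sniffed from the header).  A leading sample-ordinal
    column named ``Sample``/``sample #``/empty is recognised and dropped.
    """
    path = str(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            lines = [ln.rstrip("\n\r") for ln in fh if ln.strip()]
    except OSError as exc:
        raise SignalIOError(f"cannot read signal table {path!r}: {exc}") from exc
    if not lines:
        raise SignalIOError(f"signal table {path!r} is empty (no header)")

    delim = _sniff_delimiter(lines[0])
    header = [h.strip().strip("'\"") for h in _split(lines[0], delim)]
    skip_first = bool(header) and header[0].lower() in _INDEX_HEADERS
    leads = header[1:] if skip_first else header
    if not leads:
        raise SignalIOError(f"signal table {path!r} names no leads in its header")

    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = _split(line, delim)
        if skip_first:
            cells = cells[1:]
        if len(cells) != len(leads):
            raise SignalIOError(
                f"{path}:{lineno}: expected {len(leads)} cells, got {len(cells)}"
            )
        try:
            rows.append([int(c) for c in cells])
        except ValueError as exc:
            raise SignalIOError(f"{path}:{lineno}: non-integer cell ({exc})") from exc

    samples = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.empty((0, len(leads)), dtype=np.int64)
    )
    record_id = re.sub(r"\.(csv|txt)$", "", path.rsplit("/", 1)[-1])
    return Recording(
        record_id=record_id,
        sampling_rate=sampling_rate,
        lead_names=leads,
        samples=samples,
        unit_mode="adc",
    )


def write_signal_table(rec: Recording, path, include_index: bool = False) -> None:
    """Write a sample table readable by :func:`read_signal_table`.

    ADC-mode values are written as plain integers (no decimal points).
    """
    try:
        with open(str(path), "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            header = (["Sample"] if include_index else []) + list(rec.lead_names)
            writer.writerow(header)
            for i, row in enumerate(rec.samples):
                cells = [int(v) if rec.unit_mode == "adc" else repr(float(v)) for v in row]
                writer.writerow(([i] if include_index else []) + cells)
    except OSError as exc:
        raise SignalIOError(f"cannot write signal table {path!r}: {exc}") from exc


def read_annotation_table(path) -> AnnotationTrack:
    """Read an annotation table with columns (Time, Sample, Type).

    Events are returned sorted by sample index; out-of-order input sorts
    with a warning, duplicates are kept (with a warning).  Symbols are kept
    verbatim — no case folding.
    """
    path = str(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            lines = [ln.rstrip("\n\r") for ln in fh if ln.strip()]
    except OSError as exc:
        raise SignalIOError(f"cannot read annotation table {path!r}: {exc}") from exc
    if not lines:
        raise SignalIOError(f"annotation table {path!r} is empty (no header)")

    delim = _sniff_delimiter(lines[0])
    header = [h.strip().lower() for h in _split(lines[0], delim)]
    try:
        i_time = header.index("time")
        i_sample = header.index("sample")
        i_type = header.index("type")
    except ValueError:
        # Headerless fallback: assume the (Time, Sample, Type) column order.
        i_time, i_sample, i_type = 0, 1, 2

    events = []
    start = 1 if "sample" in header else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = _split(line, delim)
        try:
            idx = int(cells[i_sample])
        except (ValueError, IndexError) as exc:
            raise SignalIOError(f"{path}:{lineno}: bad sample index ({exc})") from exc
        if idx < 0:
            raise SignalIOError(f"{path}:{lineno}: negative sample index {idx}")
        sym = cells[i_type].strip()
        time_text = cells[i_time].strip() if i_time < len(cells) else None
        events.append((idx, sym, time_text))

    indices = [e[0] for e in events]
    if any(b < a for a, b in zip(indices, indices[1:])):
        warnings.warn(f"{path}: annotation indices out of order; sorting", stacklevel=2)
        events.sort(key=lambda e: e[0])
    if len(set(indices)) != len(indices):
        warnings.warn(f"{path}: duplicate annotation sample indices kept", stacklevel=2)

    record_id = re.sub(r"(_ann(otations)?)?\.(csv|txt)$", "", path.rsplit("/", 1)[-1])
    return AnnotationTrack(record_id=record_id, events=events)


def write_annotation_table(track: AnnotationTrack, path) -> None:
    """Write an annotation table readable by :func:`read_annotation_table`."""
    try:
        with open(str(path), "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["Time", "Sample", "Type"])
            for idx, sym, time_text in track.events:
                writer.writerow([time_text if time_text is not None else "", idx, sym])
    except OSError as exc:
        raise SignalIOError(f"cannot write annotation table {path!r}: {exc}") from exc
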