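"""Synthetic annotated single-lead ECG recordings with controllable anomalies.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed relative to
the R peak, in the spirit of dynamical ECG simulators; a normal beat spans
roughly 1.2 mV peak-to-peak.  Beats are laid down at a jittered mean RR
interval, annotated at their R-peak sample, and anomalies fire per beat as
independent Bernoulli draws from a dedicated random stream (so event
placement and signal noise are independently reproducible).

Built-in anomalous morphologies:

* ``"V"`` (premature ventricular contraction) — premature, widened,
  inverted, large beat followed by a compensatory pause;
* ``"A"`` (atrial premature beat) — premature beat of normal shape;
* ``"|"`` (isolated QRS-like artifact) — a short broadband burst.

The goal is separability and file-format fidelity, not physiological
realism: waveforms are smooth Gaussian composites, noise is white, and no
respiratory or baseline drift is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmenter import ANOMALOUS, NORMAL, SymbolMap, build_segment_dataset
from .signal_io import (
    AnnotationTrack,
    Recording,
    millivolts_to_adc,
    write_annotation_table,
    write_signal_table,
)


class SyntheticError(Exception):
    pass


#: Normal beat morphology: wave -> (amplitude mV, offset s from R, width s).
NORMAL_WAVES = {
    "P": (0.15, -0.20, 0.025),
    "Q": (-0.10, -0.030, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.18, 0.030, 0.010),
    "T": (0.30, 0.25, 0.050),
}

#: PVC: no organised P wave; wide, tall, inverted QRS; discordant T wave.
PVC_WAVES = {
    "P": (0.0, -0.20, 0.025),
    "Q": (0.10, -0.050, 0.020),
    "R": (-1.40, 0.0, 0.045),
    "S": (0.25, 0.060, 0.025),
    "T": (0.45, 0.30, 0.070),
}


@dataclass(frozen=True)
class AnomalySpec:
    """One anomalous symbol with its per-beat firing rate and morphology.

    ``waves=None`` keeps the normal morphology (timing-only anomaly);
    ``artifact=True`` replaces the beat with a broadband noise burst.
    ``premature=True`` shortens the preceding RR interval by
    ``premature_factor`` and follows the beat with a compensatory pause.
    """

    symbol: str
    rate: float
    waves: dict | None = None
    premature: bool = False
    premature_factor: float = 0.6
    artifact: bool = False

    def __post_init__(self):
        if not 0 <= self.rate <= 1:
            raise SyntheticError(f"rate must be in [0, 1], got {self.rate}")
        if not self.symbol:
            raise SyntheticError("anomaly symbol must be non-empty")


def default_anomalies(pvc_rate: float = 0.0, apb_rate: float = 0.0,
                      artifact_rate: float = 0.0) -> tuple[AnomalySpec, ...]:
    return (
        AnomalySpec("V", pvc_rate, waves=PVC_WAVES, premature=True),
        AnomalySpec("A", apb_rate, premature=True),
        AnomalySpec("|", artifact_rate, artifact=True),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated recording."""

    duration_s: float = 1800.0
    sampling_rate: float = 360.0
    mean_rr_s: float = 0.8
    rr_jitter_s: float = 0.04
    waves: dict = field(default_factory=lambda: dict(NORMAL_WAVES))
    noise_mv: float = 0.02
    anomalies: tuple[AnomalySpec, ...] = ()
    seed: int = 0
    record_id: str = "sim"

    def __post_init__(self):
        if self.duration_s <= 0 or self.sampling_rate <= 0 or self.mean_rr_s <= 0:
            raise SyntheticError("duration, sampling rate and mean RR must be positive")
        if self.mean_rr_s > self.duration_s:
            raise SyntheticError("mean RR interval exceeds the recording duration")
        for amp, off, width in self.waves.values():
            if width <= 0:
                raise SyntheticError("wave widths must be positive")


def _beat_waveform(t: np.ndarray, center: float, waves: dict) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, offset, width in waves.values():
        if amp:
            out += amp * np.exp(-0.5 * ((t - center - offset) / width) ** 2)
    return out


def simulate_recording(
    cfg: SyntheticConfig, window_seconds: float = 15.0
) -> tuple[Recording, AnnotationTrack, list[str]]:
    """Simulate one annotated recording plus ground-truth segment labels.

    Returns ``(recording, track, truth)`` where ``truth[i]`` is the label
    the segment-labeling rule assigns to window ``i`` from the *true* event
    list (one annotation per beat at its R-peak sample, ``"N"`` unless an
    anomaly fired).  Fully deterministic given ``cfg.seed``.
    """
    n_samples = int(round(cfg.duration_s * cfg.sampling_rate))
    # Independent streams: beat timing/noise vs anomaly placement.
    seed_root = np.random.SeedSequence(cfg.seed)
    rng_signal, rng_events = [np.random.default_rng(s) for s in seed_root.spawn(2)]

    # Lay down beat times, then decide per beat whether an anomaly fires.
    beats: list[tuple[float, AnomalySpec | None]] = []
    t = cfg.mean_rr_s * 0.5
    pending_pause = 0.0
    while t < cfg.duration_s - 0.05:
        fired = None
        for spec in cfg.anomalies:
            if spec.rate > 0 and rng_events.random() < spec.rate:
                fired = spec
                break
        if fired is not None and fired.premature:
            t_beat = t - (1.0 - fired.premature_factor) * cfg.mean_rr_s
            t_beat = max(t_beat, beats[-1][0] + 0.2 if beats else 0.05)
            beats.append((t_beat, fired))
            pending_pause = (1.0 - fired.premature_factor) * cfg.mean_rr_s
        else:
            beats.append((t, fired))
        rr = cfg.mean_rr_s + rng_signal.normal(0.0, cfg.rr_jitter_s) + pending_pause
        pending_pause = 0.0
        t += max(rr, 0.25)

    time = np.arange(n_samples) / cfg.sampling_rate
    mv = np.zeros(n_samples)
    events = []
    for t_beat, spec in beats:
        sample_idx = int(round(t_beat * cfg.sampling_rate))
        if sample_idx >= n_samples:
            continue
        lo = max(0, int((t_beat - 0.5) * cfg.sampling_rate))
        hi = min(n_samples, int((t_beat + 0.6) * cfg.sampling_rate))
        window = slice(lo, hi)
        if spec is not None and spec.artifact:
            burst = rng_signal.uniform(-0.8, 0.8, hi - lo)
            mv[window] += burst * np.hanning(hi - lo)
            symbol = spec.symbol
        else:
            waves = spec.waves if (spec is not None and spec.waves) else cfg.waves
            mv[window] += _beat_waveform(time[window], t_beat, waves)
            symbol = spec.symbol if spec is not None else "N"
        minutes, seconds = divmod(t_beat, 60.0)
        events.append((sample_idx, symbol, f"{int(minutes)}:{seconds:06.3f}"))
    if cfg.noise_mv > 0:
        mv += rng_signal.normal(0.0, cfg.noise_mv, n_samples)

    adc = millivolts_to_adc(mv)
    rec = Recording(
        record_id=cfg.record_id,
        sampling_rate=cfg.sampling_rate,
        lead_names=["MLII"],
        samples=adc.reshape(-1, 1),
        unit_mode="adc",
    )
    track = AnnotationTrack(record_id=cfg.record_id, events=events)
    truth = _ground_truth_labels(track, n_samples, window_seconds, cfg.sampling_rate)
    return rec, track, truth


def _ground_truth_labels(track, n_samples, window_seconds, sampling_rate):
    """Apply the window-labeling rule to the true event list."""
    seg_len = int(round(window_seconds * sampling_rate))
    n_windows = n_samples // seg_len
    anomalous = set()
    for idx, sym, _ in track.events:
        if sym != "N" and idx // seg_len < n_windows:
            anomalous.add(idx // seg_len)
    return [ANOMALOUS if i in anomalous else NORMAL for i in range(n_windows)]


def make_benchmark(
    out_dir,
    n_records: int = 4,
    duration_s: float = 120.0,
    pvc_rate: float = 0.1,
    clean_fraction: float = 0.5,
    seed: int = 0,
    window_seconds: float = 15.0,
) -> pd.DataFrame:
    """Write a directory of signal/annotation CSV pairs plus a truth manifest.

    The first ``round(clean_fraction * n_records)`` records are anomaly-free;
    the rest carry PVCs at ``pvc_rate`` per beat.  Returns the per-segment
    truth manifest (record_id, segment_index, label) that is also written to
    ``truth.csv``.  Byte-identical for identical arguments.
    """
    from pathlib import Path

    if n_records < 1:
        raise SyntheticError("n_records must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_clean = int(round(clean_fraction * n_records))
    rows = []
    for i in range(n_records):
        rate = 0.0 if i < n_clean else pvc_rate
        cfg = SyntheticConfig(
            duration_s=duration_s,
            anomalies=default_anomalies(pvc_rate=rate),
            seed=seed * 1000 + i,
            record_id=f"sim{i:02d}",
        )
        rec, track, truth = simulate_recording(cfg, window_seconds=window_seconds)
        write_signal_table(rec, out / f"{rec.record_id}.csv")
        write_annotation_table(track, out / f"{rec.record_id}_ann.csv")
        for j, label in enumerate(truth):
            rows.append(
                {"record_id": rec.record_id, "segment_index": j, "label": label}
            )
    manifest = pd.DataFrame(rows, columns=["record_id", "segment_index", "label"])
    manifest.to_csv(out / "truth.csv", index=False)
    return manifest


def make_separable_dataset(
    n_segments: int = 400,
    pvc_rate: float = 0.35,
    noise_mv: float = 0.02,
    seed: int = 0,
    window_seconds: float = 15.0,
):
    """A balanced, cleanly separable segment dataset for learnability checks.

    Half the segments come from anomaly-free recordings, half from
    recordings with PVCs at ``pvc_rate`` per beat (≈ every window hit at the
    default rate).  Labels are derived through the real segmentation +
    labeling path, not copied from the generator.
    """
    n_per_class = n_segments // 2
    datasets = []
    for cls, rate in ((NORMAL, 0.0), (ANOMALOUS, pvc_rate)):
        cfg = SyntheticConfig(
            duration_s=n_per_class * window_seconds,
            noise_mv=noise_mv,
            anomalies=default_anomalies(pvc_rate=rate),
            seed=seed + (0 if cls == NORMAL else 1),
            record_id=f"sep_{cls}",
        )
        rec, track, _ = simulate_recording(cfg, window_seconds=window_seconds)
        datasets.append(
            build_segment_dataset(rec, track, SymbolMap(), window_seconds)
        )
    from .segmenter import SegmentDataset

    merged = SegmentDataset(
        datasets[0].segments + datasets[1].segments,
        seg_len=datasets[0].seg_len,
        lead="MLII",
    )
    return merged
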