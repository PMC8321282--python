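import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from ecgscreen import (
    ModelConfig,
    ConvBlockSpec,
    Recording,
    SegmentDataset,
    Segment,
    NORMAL,
    ANOMALOUS,
)


@pytest.fixture
def two_lead_recording():
    """A short two-lead (MLII, V5) recording with recognizable values."""
    rng = np.random.default_rng(42)
    samples = rng.integers(900, 1100, size=(720, 2))
    samples[0] = (995, 1011)
    return Recording(
        record_id="rec100",
        sampling_rate=360.0,
        lead_names=["MLII", "V5"],
        samples=samples,
        unit_mode="adc",
    )


@pytest.fixture
def tiny_model_config():
    """A small but structurally complete architecture for fast training tests."""
    return ModelConfig(
        input_length=120,
        blocks=(
            ConvBlockSpec(kernel_size=10, stride=2, filters=4, pool_size=2),
            ConvBlockSpec(kernel_size=3, stride=1, filters=8, pool_size=2),
        ),
        avg_pool_size=2,
        dropout_rate=0.2,
        input_units="adc",
    )


def make_toy_segments(n_per_class=8, seg_len=120, seed=0, n_records=4):
    """Separable toy segments: the two classes differ by a constant offset."""
    rng = np.random.default_rng(seed)
    segments = []
    idx_per_record = {}
    for i in range(2 * n_per_class):
        label = NORMAL if i % 2 == 0 else ANOMALOUS
        base = 0.0 if label == NORMAL else 3.0
        rid = f"r{i % n_records}"
        j = idx_per_record.get(rid, 0)
        idx_per_record[rid] = j + 1
        segments.append(
            Segment(
                record_id=rid,
                segment_index=j,
                samples=base + rng.normal(0, 0.5, seg_len),
                label=label,
            )
        )
    return SegmentDataset(segments, seg_len=seg_len, lead="MLII")


@pytest.fixture
def toy_segments():
    return make_toy_segments()
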