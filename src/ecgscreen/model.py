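"""Declarative four-block 1D-CNN architecture with a layer-shape calculus.

The classifier stacks four convolutional blocks (Conv1D -> BatchNorm ->
MaxPool -> ReLU) over a 5400-sample single-lead input, then an output block
(AveragePool -> Flatten -> Dropout -> Dense with L2 penalty and softmax).
Convolutions are valid (no padding), pooling is non-overlapping with stride
equal to pool size — both conventions are forced by the published per-layer
output shapes and are checked by :func:`shape_trace` before any weights are
allocated.

The default configuration traces to::

    conv (666;128) -> pool (166;128) -> conv (163;256) -> pool (40;256)
    -> conv (37;256) -> pool (9;256) -> conv (8;512) -> pool (2;512)
    -> avgpool (1;512) -> flatten 512 -> dense 2

Note the fourth block uses kernel size 2: it is the only kernel consistent
with the (9;256) -> (8;512) transition under valid convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn

NORMAL_INDEX = 0
ANOMALOUS_INDEX = 1
CLASS_ORDER = ("normal", "anomalous")


class InfeasibleArchitecture(Exception):
    """A layer would produce a non-positive output length for this input."""


@dataclass(frozen=True)
class ConvBlockSpec:
    """One convolutional block: Conv1D -> BatchNorm -> MaxPool -> ReLU."""

    kernel_size: int
    stride: int
    filters: int
    pool_size: int
    activation: str = "relu"

    def __post_init__(self):
        for name in ("kernel_size", "stride", "filters", "pool_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")


#: The published four-block architecture (kernel 2 in block 4, see module doc).
DEFAULT_BLOCKS = (
    ConvBlockSpec(kernel_size=80, stride=8, filters=128, pool_size=4),
    ConvBlockSpec(kernel_size=4, stride=1, filters=256, pool_size=4),
    ConvBlockSpec(kernel_size=4, stride=1, filters=256, pool_size=4),
    ConvBlockSpec(kernel_size=2, stride=1, filters=512, pool_size=4),
)


@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 5400
    input_channels: int = 1
    blocks: tuple[ConvBlockSpec, ...] = DEFAULT_BLOCKS
    avg_pool_size: int = 2
    dropout_rate: float = 0.6
    l2_penalty: float = 0.001
    n_classes: int = 2
    input_units: str = "mv"  # "mv": affine ADC->millivolt conversion; "adc": raw

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_units not in ("mv", "adc"):
            raise ValueError("input_units must be 'mv' or 'adc'")
        object.__setattr__(self, "blocks", tuple(
            b if isinstance(b, ConvBlockSpec) else ConvBlockSpec(**b) for b in self.blocks
        ))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "blocks" in d:
            d["blocks"] = tuple(
                b if isinstance(b, ConvBlockSpec) else ConvBlockSpec(**b)
                for b in d["blocks"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ShapeTrace:
    """Ordered per-layer (name, length, channels) shape sequence."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def shapes(self) -> list[tuple[int, int]]:
        return [(length, ch) for _, length, ch in self.entries]

    def distinct_shapes(self) -> list:
        """Shape sequence with consecutive duplicates collapsed.

        Shape-preserving layers (batch norm, activation, dropout) repeat
        their predecessor's shape; collapsing them leaves the backbone
        sequence of the architecture.  Channel-less entries (flatten, dense)
        appear as bare integers.
        """
        out: list = []
        for _, length, ch in self.entries:
            item = (length, ch) if ch else length
            if not out or out[-1] != item:
                out.append(item)
        return out

    def summary(self) -> str:
        """Human-readable table: layer type and output shape."""
        lines = ["Type of Layer           Output Shape"]
        for name, length, ch in self.entries:
            shape = f"({length};{ch})" if ch else f"({length})"
            lines.append(f"{name:<24}{shape}")
        return "\n".join(lines)


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Valid-convolution output length: floor((length - kernel) / stride) + 1."""
    if stride < 1:
        raise InfeasibleArchitecture(f"stride must be >= 1, got {stride}")
    if kernel > length:
        raise InfeasibleArchitecture(
            f"kernel {kernel} exceeds input length {length}"
        )
    return (length - kernel) // stride + 1


def pool_output_length(length: int, pool: int) -> int:
    """Non-overlapping pooling output length: floor(length / pool)."""
    if pool < 1:
        raise InfeasibleArchitecture(f"pool size must be >= 1, got {pool}")
    return length // pool


def shape_trace(config: ModelConfig = ModelConfig()) -> ShapeTrace:
    """Propagate (length, channels) through every layer of the architecture.

    Raises :class:`InfeasibleArchitecture` naming the first layer whose
    output length would not be positive.
    """
    trace = ShapeTrace()
    length, channels = config.input_length, config.input_channels
    for i, blk in enumerate(config.blocks, start=1):
        try:
            length = conv_output_length(length, blk.kernel_size, blk.stride)
        except InfeasibleArchitecture as exc:
            raise InfeasibleArchitecture(f"block {i} Conv1D: {exc}") from exc
        channels = blk.filters
        trace.entries.append(("Conv1D", length, channels))
        trace.entries.append(("Batch Normalization", length, channels))
        length = pool_output_length(length, blk.pool_size)
        if length < 1:
            raise InfeasibleArchitecture(
                f"block {i} Max Pooling 1D: output length 0 (pool {blk.pool_size})"
            )
        trace.entries.append(("Max Pooling 1D", length, channels))
        trace.entries.append(("Activation", length, channels))
    length = pool_output_length(length, config.avg_pool_size)
    if length < 1:
        raise InfeasibleArchitecture("AveragePooling 1D: output length 0")
    trace.entries.append(("AveragePooling 1D", length, channels))
    flat = length * channels
    trace.entries.append(("Flatten", flat, 0))
    trace.entries.append(("Dropout", flat, 0))
    trace.entries.append(("Dense", config.n_classes, 0))
    return trace


class SegmentClassifier:
    """Trainable binary segment classifier built from a :class:`ModelConfig`.

    Class order of the softmax outputs is (normal, anomalous); exact
    probability ties resolve to anomalous — the screening system prefers a
    false alarm over a missed one.
    """

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        self.seed = seed
        self.trace = shape_trace(config)  # validates feasibility
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        channels = config.input_channels
        for i, blk in enumerate(config.blocks):
            layers.append(
                nn.Conv1D(
                    in_channels=channels,
                    filters=blk.filters,
                    kernel_size=blk.kernel_size,
                    stride=blk.stride,
                    rng=rng,
                    first_layer=(i == 0),
                )
            )
            layers.append(nn.BatchNorm(blk.filters))
            layers.append(nn.MaxPool1D(blk.pool_size))
            layers.append(nn.ReLU())
            channels = blk.filters
        layers.append(nn.AvgPool1D(config.avg_pool_size))
        layers.append(nn.Flatten())
        layers.append(nn.Dropout(config.dropout_rate, rng=rng))
        flat = self.trace.entries[-3][1]
        layers.append(nn.Dense(flat, config.n_classes, rng=rng, l2=config.l2_penalty))
        self.net = nn.Sequential(layers)

    def prepare_input(self, segments: np.ndarray) -> np.ndarray:
        """(n, seg_len) raw segment matrix -> (n, seg_len, 1) network input.

        With ``input_units="mv"`` the affine ADC-to-millivolt map is applied;
        with ``"adc"`` values pass through untouched.
        """
        x = np.asarray(segments, dtype=np.float32)
        if x.ndim != 2 or x.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected (n, {self.config.input_length}) segments, got {x.shape}"
            )
        if self.config.input_units == "mv":
            x = (x - 1024.0) * (10.0 / 2048.0)
        return x[:, :, None]

    def forward_shapes(self, batch_size: int = 2) -> list[tuple[int, ...]]:
        """Actual tensor shapes of a forward pass, for cross-checking the trace."""
        x = np.zeros((batch_size, self.config.input_length, 1), dtype=np.float32)
        shapes = []
        for layer in self.net.layers:
            x = layer.forward(x, training=False)
            shapes.append(x.shape[1:])
        return shapes

    def predict_proba(self, segments: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """(n, 2) class probabilities in (normal, anomalous) order."""
        x = self.prepare_input(segments)
        out = [
            self.net.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out) if out else np.empty((0, self.config.n_classes))

    def predict_labels(self, segments: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Integer labels (0 normal, 1 anomalous); 0.5/0.5 ties go anomalous."""
        probs = self.predict_proba(segments, batch_size=batch_size)
        return label_from_proba(probs)


def label_from_proba(probs: np.ndarray) -> np.ndarray:
    """Argmax with ties resolved to the anomalous class."""
    probs = np.asarray(probs)
    return (probs[:, ANOMALOUS_INDEX] >= probs[:, NORMAL_INDEX]).astype(np.int64)


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> SegmentClassifier:
    """Construct a seeded, trainable classifier after validating feasibility."""
    return SegmentClassifier(config, seed=seed)
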