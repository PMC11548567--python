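"""Declarative 1D-CNN architecture and a framework-free shape/parameter engine.

The network that classifies raw respiratory-cycle waveforms is described
declaratively as an ordered list of :class:`LayerSpec`.  :func:`summarize`
propagates (length, channels) through the stack with plain arithmetic —
valid convolution, floor-division max-pooling — and accumulates per-layer
trainable-parameter counts, so the reference layer table can be reproduced
and regression-tested without loading any learning framework.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

LayerKind = Literal["conv1d", "maxpool1d", "dropout", "flatten", "dense"]
Activation = Literal["relu", "softmax", "none"]


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network.

    Only the fields relevant to ``kind`` are used: ``filters``/``kernel`` for
    conv1d, ``pool`` for maxpool1d, ``rate`` for dropout, ``units`` for dense.
    """

    kind: LayerKind
    filters: int = 0
    kernel: int = 0
    pool: int = 0
    rate: float = 0.0
    units: int = 0
    activation: Activation = "none"

    def __post_init__(self) -> None:
        if self.kind == "conv1d" and (self.filters < 1 or self.kernel < 1):
            raise ValueError("conv1d needs filters >= 1 and kernel >= 1")
        if self.kind == "maxpool1d" and self.pool < 1:
            raise ValueError("maxpool1d needs pool >= 1")
        if self.kind == "dense" and self.units < 1:
            raise ValueError("dense needs units >= 1")
        if self.kind == "dropout" and not 0.0 <= self.rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass(frozen=True)
class ArchSpec:
    """Full network description: input shape plus an ordered layer stack."""

    input_len: int
    input_channels: int
    layers: tuple[LayerSpec, ...]

    def __post_init__(self) -> None:
        if self.input_len < 1 or self.input_channels < 1:
            raise ValueError("input_len and input_channels must be >= 1")
        object.__setattr__(self, "layers", tuple(self.layers))


@dataclass(frozen=True)
class LayerSummary:
    """One row of the layer table: name, output shape, parameter count."""

    name: str
    out_len: int  # sequence length before flatten; units after
    out_channels: int  # channels before flatten; 1 after
    params: int


@dataclass(frozen=True)
class ArchSummary:
    rows: tuple[LayerSummary, ...]
    total_params: int

    def as_text(self) -> str:
        lines = [f"{'Layer':<16}{'Output shape':<20}{'Param #':>12}"]
        for r in self.rows:
            shape = (
                f"(None, {r.out_len}, {r.out_channels})"
                if r.out_channels > 1 or r.name.startswith(("input", "conv", "max", "drop"))
                else f"(None, {r.out_len})"
            )
            lines.append(f"{r.name:<16}{shape:<20}{r.params:>12,}")
        lines.append(f"{'total':<36}{self.total_params:>12,}")
        return "\n".join(lines)


def conv_out_len(length: int, kernel: int) -> int:
    """Output length of a valid (unpadded), stride-1 convolution: L - k + 1."""
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    if kernel > length:
        raise ValueError(f"kernel {kernel} longer than input {length}")
    return length - kernel + 1


def pool_out_len(length: int, pool: int) -> int:
    """Output length of max-pooling with stride = pool width, no padding."""
    if pool < 1:
        raise ValueError("pool must be >= 1")
    return length // pool


def layer_params(spec: LayerSpec, in_channels_or_units: int) -> int:
    """Trainable parameters of one layer given its fan-in.

    conv1d: kernel * in_channels * filters + filters (bias);
    dense: in_units * units + units; all other layers carry no parameters.
    """
    if spec.kind == "conv1d":
        return spec.kernel * in_channels_or_units * spec.filters + spec.filters
    if spec.kind == "dense":
        return in_channels_or_units * spec.units + spec.units
    return 0


def summarize(arch: ArchSpec) -> ArchSummary:
    """Propagate shapes through the stack and count parameters per layer.

    Pure arithmetic: no weights are allocated.  Raises ``ValueError`` naming
    the offending layer if a convolution kernel no longer fits the sequence
    (shape collapse).
    """
    rows = [LayerSummary("input", arch.input_len, arch.input_channels, 0)]
    length, channels = arch.input_len, arch.input_channels
    flat: int | None = None  # units once the stack is flattened
    counters: dict[str, int] = {}

    for spec in arch.layers:
        idx = counters.get(spec.kind, 0)
        counters[spec.kind] = idx + 1
        name = spec.kind if idx == 0 else f"{spec.kind}_{idx}"
        if spec.kind == "conv1d":
            if flat is not None:
                raise ValueError(f"{name}: conv1d after flatten")
            if spec.kernel > length:
                raise ValueError(
                    f"{name}: kernel {spec.kernel} exceeds sequence length {length}"
                )
            p = layer_params(spec, channels)
            length = conv_out_len(length, spec.kernel)
            channels = spec.filters
            rows.append(LayerSummary(name, length, channels, p))
        elif spec.kind == "maxpool1d":
            if flat is not None:
                raise ValueError(f"{name}: maxpool1d after flatten")
            length = pool_out_len(length, spec.pool)
            if length < 1:
                raise ValueError(f"{name}: pooling collapsed the sequence")
            rows.append(LayerSummary(name, length, channels, 0))
        elif spec.kind == "dropout":
            if flat is None:
                rows.append(LayerSummary(name, length, channels, 0))
            else:
                rows.append(LayerSummary(name, flat, 1, 0))
        elif spec.kind == "flatten":
            if flat is not None:
                raise ValueError(f"{name}: repeated flatten")
            flat = length * channels
            rows.append(LayerSummary(name, flat, 1, 0))
        elif spec.kind == "dense":
            if flat is None:
                raise ValueError(f"{name}: dense before flatten")
            p = layer_params(spec, flat)
            flat = spec.units
            rows.append(LayerSummary(name, flat, 1, p))
        else:  # pragma: no cover - guarded by LayerSpec validation
            raise ValueError(f"unknown layer kind {spec.kind!r}")

    return ArchSummary(tuple(rows), sum(r.params for r in rows))


# Kernel widths (13, 11, 9, 7) and pool width 3 are not printed in the layer
# table; they are the unique valid-convolution / floor-pooling solutions of its
# length transitions, e.g. 8000 - k + 1 = 7988 => k = 13 and
# floor(7988 / p) = 2662 => p = 3.
_CONV = [(8, 13), (16, 11), (32, 9), (64, 7)]
_DENSE = [256, 128, 64]


def default_arch(
    n_classes: int = 4,
    dropout_rate: float = 0.3,
    input_len: int = 8000,
) -> ArchSpec:
    """The reference raw-waveform classifier.

    Four conv(relu)->maxpool(3)->dropout blocks with filters doubling
    8->16->32->64 and kernels shrinking 13->11->9->7, then flatten and a
    256->128->64 dense funnel (dropout after each) into a softmax head.
    """
    layers: list[LayerSpec] = []
    for filters, kernel in _CONV:
        layers.append(LayerSpec("conv1d", filters=filters, kernel=kernel, activation="relu"))
        layers.append(LayerSpec("maxpool1d", pool=3))
        layers.append(LayerSpec("dropout", rate=dropout_rate))
    layers.append(LayerSpec("flatten"))
    for units in _DENSE:
        layers.append(LayerSpec("dense", units=units, activation="relu"))
        layers.append(LayerSpec("dropout", rate=dropout_rate))
    layers.append(LayerSpec("dense", units=n_classes, activation="softmax"))
    return ArchSpec(input_len=input_len, input_channels=1, layers=tuple(layers))


def scaled_arch(
    base_filters: int,
    base_kernel: int,
    dropout_rate: float,
    base_units: int,
    n_conv_blocks: int = 4,
    n_classes: int = 4,
    input_len: int = 8000,
    pool: int = 3,
) -> ArchSpec:
    """Architecture family indexed by the tuning grid's scalar knobs.

    The grid gives one filter count / kernel width / unit count per
    configuration while the reference net has four conv blocks and three dense
    layers, so the knobs are treated as first-layer base values with the
    reference progression applied: filters double and kernels shrink by 2 per
    block (floored at 1, kept odd), dense units halve per layer (floored at 4).
    """
    layers: list[LayerSpec] = []
    for i in range(n_conv_blocks):
        k = max(base_kernel - 2 * i, 1)
        layers.append(
            LayerSpec("conv1d", filters=base_filters * 2**i, kernel=k, activation="relu")
        )
        layers.append(LayerSpec("maxpool1d", pool=pool))
        layers.append(LayerSpec("dropout", rate=dropout_rate))
    layers.append(LayerSpec("flatten"))
    units = base_units
    for _ in range(3):
        layers.append(LayerSpec("dense", units=max(units, 4), activation="relu"))
        layers.append(LayerSpec("dropout", rate=dropout_rate))
        units //= 2
    layers.append(LayerSpec("dense", units=n_classes, activation="softmax"))
    return ArchSpec(input_len=input_len, input_channels=1, layers=tuple(layers))
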