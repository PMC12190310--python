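"""Per-modality 3-D convolutional feature encoder.

The default configuration is the full-size network used for real brain
volumes: nine 3x3x3 valid convolutions (stride 1, no padding) with channel
widths 8, 8, 16, 16, 32, 32, 64, 64, 128, each followed by batch norm and
leaky ReLU, and stride-2 max pooling after layers 2, 4, 6 and 8.  On a
113 x 137 x 113 input the spatial trace ends at (1, 2, 1), so the flattened
per-modality feature has 128 * 2 = 256 entries.

``shape_trace`` performs that bookkeeping analytically (pure integer
arithmetic), and every ``Encoder3D`` validates its input shape against it, so
mis-sized volumes fail with a named layer rather than a cryptic broadcast
error deep in the forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor
from . import nn

__all__ = ["EncoderConfig", "ConfigurationError", "shape_trace", "Encoder3D",
           "flatten_features", "FULL_INPUT_SHAPE"]

#: spatial size of preprocessed real MRI/PET volumes
FULL_INPUT_SHAPE = (113, 137, 113)


class ConfigurationError(ValueError):
    """An encoder configuration that cannot process the declared input shape."""


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of one encoder branch.

    Parameters
    ----------
    channels
        Output channels of each conv layer, in order.
    kernel
        Cubic kernel edge length (odd).
    pool_after
        1-based indices of conv layers followed by a stride-2 max pool.
    leaky_slope
        Negative slope of the leaky-ReLU activations.
    batch_norm
        Whether each conv is followed by batch normalisation.
    """

    channels: tuple[int, ...] = (8, 8, 16, 16, 32, 32, 64, 64, 128)
    kernel: int = 3
    pool_after: frozenset[int] = field(default_factory=lambda: frozenset({2, 4, 6, 8}))
    leaky_slope: float = 0.01
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigurationError("channels must be non-empty")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ConfigurationError(f"kernel must be odd and positive, got {self.kernel}")
        bad = set(self.pool_after) - set(range(1, len(self.channels) + 1))
        if bad:
            raise ConfigurationError(f"pool_after indices {sorted(bad)} outside layer range")


def toy_encoder_config(channels: tuple[int, ...] = (4, 8),
                       pool_after: frozenset[int] = frozenset({1, 2})) -> EncoderConfig:
    """A desk-scale encoder for tests and synthetic experiments."""
    return EncoderConfig(channels=channels, pool_after=frozenset(pool_after))


def shape_trace(config: EncoderConfig, input_shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
    """Spatial shape after each conv (+ optional pool) layer.

    Valid convolution shrinks each dimension by ``kernel - 1``; a stride-2
    pool then floor-halves it.  Raises :class:`ConfigurationError` naming the
    first layer at which any dimension would drop below 1.
    """
    if len(input_shape) != 3 or any(s < 1 for s in input_shape):
        raise ConfigurationError(f"input shape must be 3 positive ints, got {input_shape}")
    shapes: list[tuple[int, int, int]] = []
    current = tuple(int(s) for s in input_shape)
    for layer in range(1, len(config.channels) + 1):
        current = tuple(s - (config.kernel - 1) for s in current)
        if min(current) < 1:
            raise ConfigurationError(
                f"conv layer {layer} reduces spatial shape to {current}; "
                f"input {input_shape} is too small for this configuration")
        if layer in config.pool_after:
            current = tuple(s // 2 for s in current)
            if min(current) < 1:
                raise ConfigurationError(
                    f"pool after layer {layer} reduces spatial shape to {current}; "
                    f"input {input_shape} is too small for this configuration")
        shapes.append(current)
    return shapes


def feature_dim(config: EncoderConfig, input_shape: tuple[int, int, int]) -> int:
    """Flattened length C*D*H*W of one encoder branch's output."""
    d, h, w = shape_trace(config, input_shape)[-1]
    return config.channels[-1] * d * h * w


class Encoder3D(nn.Module):
    """One encoder branch (a single modality in a single domain)."""

    def __init__(self, config: EncoderConfig, input_shape: tuple[int, int, int],
                 rng: np.random.Generator, in_channels: int = 1) -> None:
        super().__init__()
        self.config = config
        self.input_shape = tuple(int(s) for s in input_shape)
        self.trace = shape_trace(config, input_shape)
        self.convs: list[nn.Conv3d] = []
        self.norms: list[nn.BatchNorm3d] = []
        prev = in_channels
        for ch in config.channels:
            self.convs.append(nn.Conv3d(prev, ch, config.kernel, rng))
            self.norms.append(nn.BatchNorm3d(ch) if config.batch_norm else None)
            prev = ch
        self.norms = [n for n in self.norms if n is not None] if config.batch_norm else []

    @property
    def out_channels(self) -> int:
        return self.config.channels[-1]

    @property
    def out_shape(self) -> tuple[int, int, int]:
        return self.trace[-1]

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 4:  # (B, D, H, W) -> add channel axis
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        if tuple(x.shape[2:]) != self.input_shape:
            raise ConfigurationError(
                f"encoder built for input {self.input_shape}, got {tuple(x.shape[2:])}")
        pool = nn.MaxPool3d()
        for i, conv in enumerate(self.convs, start=1):
            x = conv(x)
            if self.config.batch_norm:
                x = self.norms[i - 1](x)
            x = x.leaky_relu(self.config.leaky_slope)
            if i in self.config.pool_after:
                x = pool(x)
        return x


def flatten_features(feature_map: Tensor) -> Tensor:
    """Row-major flatten of a (B, C, D, H, W) feature map to (B, C*D*H*W)."""
    b = feature_map.shape[0]
    return feature_map.reshape(b, int(np.prod(feature_map.shape[1:])))
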