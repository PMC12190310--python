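"""Category classifier, domain discriminator and gradient reversal.

Both heads are three fully connected layers (128, 64, 2 units) with leaky
ReLU activations, dropout after the two hidden layers, and a softmax output.
The discriminator sees fused features through a gradient-reversal layer:
the forward pass is the identity, while the backward pass multiplies the
gradient flowing toward the feature path by -lambda (lambda = 0.1), so the
encoders and fusion learn to *increase* the domain-discrimination loss the
discriminator decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, concatenate
from . import nn
from .nn import gradient_reverse

__all__ = ["HeadConfig", "ClassifierHead", "DomainDiscriminator", "gradient_reverse"]


@dataclass(frozen=True)
class HeadConfig:
    """layer_units: fully connected widths ending in 2; dropout_rate applied
    after each hidden layer; grl_weight: gradient-reversal magnitude lambda."""

    layer_units: tuple[int, ...] = (128, 64, 2)
    dropout_rate: float = 0.5
    grl_weight: float = 0.1

    def __post_init__(self) -> None:
        if not self.layer_units or self.layer_units[-1] != 2:
            raise ValueError(f"layer_units must end in 2, got {self.layer_units}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


class _Mlp(nn.Module):
    def __init__(self, in_dim: int, config: HeadConfig, rng: np.random.Generator,
                 leaky_slope: float = 0.01) -> None:
        super().__init__()
        self.config = config
        self.leaky_slope = leaky_slope
        self.layers: list[nn.Linear] = []
        self.dropouts: list[nn.Dropout] = []
        prev = in_dim
        for units in config.layer_units:
            self.layers.append(nn.Linear(prev, units, rng))
            prev = units
        for _ in config.layer_units[:-1]:
            self.dropouts.append(nn.Dropout(config.dropout_rate))

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for d in self.dropouts:
            d.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers[:-1]):
            x = layer(x).leaky_relu(self.leaky_slope)
            x = self.dropouts[i](x)
        logits = self.layers[-1](x)
        return logits.softmax(axis=-1)


class ClassifierHead(_Mlp):
    """Category classifier C_S: fused source features -> class probabilities."""

    def classify(self, fused: Tensor) -> Tensor:
        return self(fused)


class DomainDiscriminator(_Mlp):
    """Domain discriminator C_D behind the gradient-reversal layer.

    Output rows are (P(target), P(source)): column index matches the domain
    indicator, y^D = 1 for source samples and 0 for target samples.
    """

    def forward(self, fused: Tensor) -> Tensor:
        reversed_feats = gradient_reverse(fused, self.config.grl_weight)
        return super().forward(reversed_feats)

    def discriminate(self, fused_source: Tensor, fused_target: Tensor) -> tuple[Tensor, np.ndarray]:
        """Concatenate source and target fused batches, return probability
        rows (in concatenation order) and the matching domain indicators."""
        if fused_source.shape[0] == 0 or fused_target.shape[0] == 0:
            raise ValueError("both source and target batches must be non-empty")
        stacked = concatenate([fused_source, fused_target], axis=0)
        indicators = np.concatenate([np.ones(fused_source.shape[0], dtype=int),
                                     np.zeros(fused_target.shape[0], dtype=int)])
        return self(stacked), indicators
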