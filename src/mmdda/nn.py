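"""Neural-network layers on top of the :mod:`mmdda._autograd` tape.

Layers follow the familiar ``Module`` idiom: parameters are
``Tensor(requires_grad=True)``, ``train()``/``eval()`` toggle dropout and
batch-norm behaviour, and ``named_parameters`` walks submodules so optimizers
and checkpoints can address every weight by a stable dotted name.

3-D convolution is the valid (no-padding) cross-correlation used throughout
the encoder; forward and both backward passes are expressed with
``scipy.signal`` n-d correlation/convolution, which switches to FFT when the
volumes are large.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from scipy import signal

from ._autograd import Tensor

__all__ = [
    "Module",
    "Conv3d",
    "BatchNorm3d",
    "MaxPool3d",
    "Linear",
    "Dropout",
    "gradient_reverse",
    "kaiming_init",
]


def kaiming_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He/Kaiming fan-in normal init, the standard choice for (leaky-)ReLU nets."""
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


class Module:
    """Base class: parameter registry, train/eval mode, state dict."""

    def __init__(self) -> None:
        self.training = True

    def train(self) -> "Module":
        self.training = True
        for child in self._children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for child in self._children():
            child.eval()
        return self

    def _children(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update(self._buffers())
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        buffers = dict(self._named_buffer_refs())
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)
        for name, (owner, attr) in buffers.items():
            if name in state:
                setattr(owner, attr, np.array(state[name], dtype=np.float64))

    def _buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {name: getattr(owner, attr).copy()
                for name, (owner, attr) in self._named_buffer_refs(prefix)}

    def _named_buffer_refs(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._named_buffer_refs(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffer_refs(f"{key}.{i}.")
        for attr in getattr(self, "_buffer_names", ()):
            yield f"{prefix}{attr}", (self, attr)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _correlate_valid(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    return signal.correlate(x, k, mode="valid")


class Conv3d(Module):
    """Valid 3-D cross-correlation, stride 1, no padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel ** 3
        self.weight = Tensor(kaiming_init(rng, (out_channels, in_channels) + (kernel,) * 3, fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        data, w, b = x.data, self.weight, self.bias
        batch, cin = data.shape[:2]
        if cin != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {cin}")
        out_spatial = tuple(s - self.kernel + 1 for s in data.shape[2:])
        y = np.empty((batch, self.out_channels) + out_spatial)
        for n in range(batch):
            for o in range(self.out_channels):
                acc = _correlate_valid(data[n, 0], w.data[o, 0])
                for c in range(1, cin):
                    acc += _correlate_valid(data[n, c], w.data[o, c])
                y[n, o] = acc + b.data[o]
        out = Tensor(y, requires_grad=x.requires_grad or w.requires_grad or b.requires_grad,
                     _prev=(x, w, b))

        def _backward(g):
            if w.requires_grad:
                gw = np.zeros_like(w.data)
                for n in range(batch):
                    for o in range(self.out_channels):
                        for c in range(cin):
                            gw[o, c] += _correlate_valid(data[n, c], g[n, o])
                w._accumulate(gw)
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3, 4)))
            if x.requires_grad:
                gx = np.zeros_like(data)
                for n in range(batch):
                    for o in range(self.out_channels):
                        for c in range(cin):
                            gx[n, c] += signal.convolve(g[n, o], w.data[o, c], mode="full")
                x._accumulate(gx)

        out._backward = _backward
        return out


class MaxPool3d(Module):
    """2x2x2 max pooling with stride 2 (floor division on odd dims)."""

    def forward(self, x: Tensor) -> Tensor:
        b, c, d, h, w = x.data.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        if min(d2, h2, w2) < 1:
            raise ValueError(f"spatial dims {(d, h, w)} too small to pool")
        cropped = x.data[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        win = cropped.reshape(b, c, d2, 2, h2, 2, w2, 2)
        win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d2, h2, w2, 8)
        idx = win.argmax(axis=-1)
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        out = Tensor(y, requires_grad=x.requires_grad, _prev=(x,))

        def _backward(g):
            gwin = np.zeros((b, c, d2, h2, w2, 8))
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            gwin = gwin.reshape(b, c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
            gx = np.zeros_like(x.data)
            gx[:, :, : 2 * d2, : 2 * h2, : 2 * w2] = gwin.reshape(b, c, 2 * d2, 2 * h2, 2 * w2)
            x._accumulate(gx)

        out._backward = _backward
        return out


class BatchNorm3d(Module):
    """Per-channel batch norm over (batch, depth, height, width).

    Running statistics make eval-mode inference deterministic even at the
    batch size of 1 used during training.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        shape = (1, self.channels, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            n = x.data.size / self.channels
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(kaiming_init(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ValueError(f"expected {self.in_features} features, got {x.shape[-1]}")
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; the mask comes from an externally seeded generator."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without a seeded generator")
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


def gradient_reverse(x: Tensor, lam: float) -> Tensor:
    """Identity forward; backward multiplies the gradient by ``-lam``.

    The reversal makes the feature path ascend the domain-discrimination loss
    that the discriminator itself descends, which is the adversarial game.
    """
    out = Tensor(x.data, requires_grad=x.requires_grad, _prev=(x,))
    out._backward = lambda g: x._accumulate(-lam * g)
    return out
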