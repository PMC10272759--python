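"""Layer primitives built on the autograd core.

Each layer owns its parameter tensors and exposes ``__call__`` building graph
nodes, plus ``parameters()`` for the optimizer.  Initialization is Glorot
uniform from an explicit ``numpy.random.Generator`` so that model builds are
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def parameters(self) -> list[Tensor]:
        return []


class Dense(Layer):
    def __init__(self, rng, in_dim: int, out_dim: int, activation: str | None = "relu"):
        self.w = Tensor(glorot(rng, (in_dim, out_dim), in_dim, out_dim), name="dense_w")
        self.b = Tensor(np.zeros(out_dim, dtype=DTYPE), name="dense_b")
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.add(ag.matmul(x, self.w), self.b)
        if self.activation == "relu":
            out = ag.relu(out)
        return out

    def parameters(self):
        return [self.w, self.b]


class Conv1D(Layer):
    """Same-padded stride-1 1D convolution with optional ReLU."""

    def __init__(self, rng, in_ch: int, filters: int, kernel: int = 3, activation: str | None = "relu"):
        fan_in, fan_out = kernel * in_ch, kernel * filters
        self.w = Tensor(glorot(rng, (kernel, in_ch, filters), fan_in, fan_out), name="conv1d_w")
        self.b = Tensor(np.zeros(filters, dtype=DTYPE), name="conv1d_b")
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.conv1d(x, self.w, self.b)
        if self.activation == "relu":
            out = ag.relu(out)
        return out

    def parameters(self):
        return [self.w, self.b]


class Conv2D(Layer):
    def __init__(self, rng, in_ch: int, filters: int, kernel: int = 3,
                 activation: str | None = "relu", stride: tuple = (1, 1)):
        fan_in, fan_out = kernel * kernel * in_ch, kernel * kernel * filters
        self.w = Tensor(
            glorot(rng, (kernel, kernel, in_ch, filters), fan_in, fan_out), name="conv2d_w"
        )
        self.b = Tensor(np.zeros(filters, dtype=DTYPE), name="conv2d_b")
        self.activation = activation
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.conv2d(x, self.w, self.b, stride=self.stride)
        if self.activation == "relu":
            out = ag.relu(out)
        return out

    def parameters(self):
        return [self.w, self.b]


class ChannelNorm(Layer):
    """Per-position normalization over the channel axis (layer normalization)."""

    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), name="ln_gamma")
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), name="ln_beta")

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layernorm(x, self.gamma, self.beta)

    def parameters(self):
        return [self.gamma, self.beta]


class LSTM(Layer):
    """Unidirectional LSTM over (B, T, C).

    ``return_sequences`` controls whether the full hidden sequence (B, T, H)
    or only the final state (B, H) is returned.  Gate order: input, forget,
    cell, output, packed in a single (C+H, 4H) kernel.
    """

    def __init__(self, rng, in_dim: int, hidden: int, return_sequences: bool = False):
        self.hidden = hidden
        self.wx = Tensor(glorot(rng, (in_dim, 4 * hidden), in_dim, hidden), name="lstm_wx")
        self.wh = Tensor(glorot(rng, (hidden, 4 * hidden), hidden, hidden), name="lstm_wh")
        b = np.zeros(4 * hidden, dtype=DTYPE)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias 1: standard stabilizer
        self.b = Tensor(b, name="lstm_b")
        self.return_sequences = return_sequences

    def __call__(self, x: Tensor) -> Tensor:
        return ag.lstm_forward(x, self.wx, self.wh, self.b,
                               return_sequences=self.return_sequences)

    def parameters(self):
        return [self.wx, self.wh, self.b]


def collect_parameters(layers) -> list[Tensor]:
    params: list[Tensor] = []
    for layer in layers:
        params.extend(layer.parameters())
    return params
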