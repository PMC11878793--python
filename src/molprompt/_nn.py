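"""Shared neural-net helpers built on the autodiff tensors."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["glorot", "zeros_param", "softmax_rows", "layer_norm_rows"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros_param(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def softmax_rows(x: Tensor) -> Tensor:
    """Numerically stable softmax along the last axis."""
    shift = Tensor(x.data.max(axis=-1, keepdims=True))  # constant, no grad needed
    e = (x - shift).exp()
    return e / e.sum(axis=-1, keepdims=True)


def layer_norm_rows(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization along the last axis with learnable scale/shift."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta
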