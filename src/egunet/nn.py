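"""Neural-network layers on top of the autograd core.

Mirrors the familiar ``Module``/``Parameter`` layout: modules register child
modules and parameters by attribute assignment, ``parameters()`` walks the
tree, and ``train()``/``eval()`` toggle normalisation and stochastic-depth
behaviour. Calling a module pushes its registered name onto the active
:class:`~egunet._tensor.MacCounter` scope stack so budget reports can be
broken down per block.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import _tensor as F
from ._tensor import MacCounter, ShapeRef, Tensor

__all__ = [
    "Module", "Parameter", "Sequential", "Conv2d", "DepthwiseConv2d",
    "BatchNorm2d", "GroupNorm", "GELU", "ReLU", "Sigmoid", "Tanh",
    "Identity", "DropPath",
]


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "training", True)
        object.__setattr__(self, "_scope", type(self).__name__)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
            value._scope = name
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        counter = MacCounter._active
        if counter is not None:
            counter.scope_stack.append(self._scope)
            try:
                return self.forward(*args, **kwargs)
            finally:
                counter.scope_stack.pop()
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- tree walking --------------------------------------------------------
    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self) -> Iterator[Parameter]:
        for m in self.modules():
            yield from m._params.values()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, m in self._modules.items():
            yield from m.named_parameters(prefix + cname + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state (plain dict of arrays; used for checkpoints) ------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        i = 0
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
                i += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name]).copy()
        i = 0
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bn{i}.running_mean"]).copy()
                m.running_var = np.asarray(state[f"__bn{i}.running_var"]).copy()
                i += 1


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"_{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype):
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    """Dense 2D convolution (cross-correlation), optional bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k * k
        if rng is None:
            w = np.zeros((out_channels, in_channels, k, k), dtype=dtype)
        else:
            w = _kaiming(rng, (out_channels, in_channels, k, k), fan_in, dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    """Per-channel 2D convolution (depth multiplier 1)."""

    def __init__(self, channels: int, kernel_size: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        k = kernel_size
        if padding is None:
            padding = k // 2
        if rng is None:
            w = np.zeros((channels, k, k), dtype=dtype)
        else:
            w = _kaiming(rng, (channels, k, k), k * k, dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(channels, dtype=dtype)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.weight = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        return F.batch_norm(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        if channels % groups:
            raise ValueError(f"GroupNorm: {channels} channels not divisible by {groups} groups")
        self.weight = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self.groups, self.eps = groups, eps

    def forward(self, x):
        return F.group_norm(x, self.weight, self.bias, self.groups, self.eps)


class GELU(Module):
    def forward(self, x):
        return F.gelu(x)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


class Tanh(Module):
    def forward(self, x):
        return F.tanh(x)


class Identity(Module):
    def forward(self, x):
        return x


class DropPath(Module):
    """Stochastic depth: drop the whole residual branch per sample.

    Inactive (identity) in eval mode or at rate 0; surviving branches are
    rescaled by 1/(1-rate) so the expectation is unchanged.
    """

    def __init__(self, rate: float = 0.0, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate <= 1.0:
            raise ValueError("drop-path rate must be in [0, 1]")
        self.rate = rate
        self.rng = rng

    def forward(self, x):
        if isinstance(x, ShapeRef) or not self.training or self.rate == 0.0:
            return x
        if self.rate >= 1.0:
            return F.mul(x, 0.0)
        rng = self.rng if self.rng is not None else np.random.default_rng()
        keep = (rng.random((x.shape[0], 1, 1, 1)) >= self.rate).astype(x.dtype)
        return F.mul(x, keep / (1.0 - self.rate))
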