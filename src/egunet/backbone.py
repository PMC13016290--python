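"""Hierarchical convolutional encoder.

The segmentation network treats its encoder as a pluggable component that
must deliver four feature stages E1..E4 at resolutions H/2..H/16 with
non-decreasing channel counts. This module ships a plain convolutional
reference backbone with that interface: a strided 3x3 stem (x2 downsample),
then four stages of 3x3 conv + BN + GELU blocks with strided transitions
between stages. E_i is the output of stage i *before* the transition to
stage i+1, so E_i sits at spatial size (H/2^i, W/2^i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._tensor import ShapeRef, Tensor
from .errors import ConfigError, ShapeError

__all__ = ["BackboneConfig", "EncoderOutput", "ConvBackbone", "encode"]


@dataclass(frozen=True)
class BackboneConfig:
    """Reference encoder hyperparameters.

    stage_channels are the widths c1..c4 of E1..E4 (must be non-decreasing);
    blocks_per_stage is the number of conv blocks in each stage.
    """

    in_channels: int = 1
    stage_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    stem_downsample: int = 2
    blocks_per_stage: tuple[int, int, int, int] = (2, 2, 2, 2)

    def validate(self) -> "BackboneConfig":
        c = self.stage_channels
        if len(c) != 4 or any(ch <= 0 for ch in c):
            raise ConfigError("stage_channels must be 4 positive counts")
        if list(c) != sorted(c):
            raise ConfigError(f"stage_channels must be non-decreasing, got {c}")
        if self.in_channels <= 0:
            raise ConfigError("in_channels must be positive")
        if self.stem_downsample != 2:
            raise ConfigError("reference backbone supports stem_downsample=2 only")
        if len(self.blocks_per_stage) != 4 or any(b < 1 for b in self.blocks_per_stage):
            raise ConfigError("blocks_per_stage must be 4 counts >= 1")
        return self


@dataclass
class EncoderOutput:
    """The four stage features E1..E4 (each [N, c_i, H/2^i, W/2^i])."""

    stages: list

    def __post_init__(self):
        if len(self.stages) != 4:
            raise ShapeError(f"expected 4 encoder stages, got {len(self.stages)}")

    def __iter__(self):
        return iter(self.stages)

    def __getitem__(self, i):
        return self.stages[i]


def _conv_block(c_in: int, c_out: int, stride: int, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(c_in, c_out, 3, stride=stride, padding=1, rng=rng),
        nn.BatchNorm2d(c_out),
        nn.GELU(),
    )


class ConvBackbone(nn.Module):
    """Reference CNN encoder producing E1..E4."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        config.validate()
        self.config = config
        c = config.stage_channels
        self.stem = _conv_block(config.in_channels, c[0], stride=2, rng=rng)
        names = []
        prev = c[0]
        for i in range(4):
            blocks = [_conv_block(prev if j == 0 else c[i], c[i], 1, rng)
                      for j in range(config.blocks_per_stage[i])]
            stage = nn.Sequential(*blocks)
            setattr(self, f"stage{i + 1}", stage)
            if i < 3:
                setattr(self, f"down{i + 1}", _conv_block(c[i], c[i + 1], stride=2, rng=rng))
            prev = c[i + 1] if i < 3 else c[i]
            names.append(f"stage{i + 1}")
        self._stage_names = names

    def forward(self, x) -> EncoderOutput:
        if not isinstance(x, ShapeRef) and not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        if x.ndim == 3:
            from ._tensor import reshape

            x = reshape(x, (1,) + tuple(x.shape))
        n_axes_hw = x.shape[-2:]
        h, w = int(n_axes_hw[0]), int(n_axes_hw[1])
        if h % 16 or w % 16:
            raise ShapeError(f"input spatial size {(h, w)} must be divisible by 16")
        if not isinstance(x, ShapeRef) and not np.all(np.isfinite(x.data)):
            raise ValueError("non-finite values in encoder input")
        feats = []
        cur = self.stem(x)
        for i in range(4):
            cur = getattr(self, f"stage{i + 1}")(cur)
            feats.append(cur)
            if i < 3:
                cur = getattr(self, f"down{i + 1}")(cur)
        return EncoderOutput(feats)


def encode(image, config: BackboneConfig, seed: int = 0) -> EncoderOutput:
    """Build a freshly initialised reference backbone and encode one image.

    Convenience wrapper used by tests and exploratory code; training keeps a
    persistent backbone inside the full model instead.
    """
    net = ConvBackbone(config, rng=np.random.default_rng(seed)).eval()
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[None]
    return net(Tensor(arr))
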