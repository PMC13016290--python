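"""Edge-attention refinement of skip-connection features.

Raw encoder features routed through skip connections carry background
clutter that blurs organ boundaries after fusion. This module sharpens them
in four steps: a learned 3x3 depthwise convolution acting as a high-pass
edge detector; a squeeze/restore pair of 1x1 convolutions with a sigmoid
producing per-element edge-attention weights; concatenation of the original
and attention-weighted features compressed back to C channels; and a final
depthwise 3x3 refinement. Output shape always equals input shape, so the
module can be dropped onto any subset of skips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as F
from . import nn
from .errors import ConfigError

__all__ = ["EafConfig", "EdgeAttentionFusion", "eaf_forward"]


@dataclass(frozen=True)
class EafConfig:
    channels: int
    reduction_ratio: int = 4

    def validate(self) -> "EafConfig":
        if self.reduction_ratio < 1:
            raise ConfigError("reduction ratio must be >= 1")
        if self.channels % self.reduction_ratio:
            raise ConfigError(
                f"channels ({self.channels}) must be divisible by reduction ratio "
                f"({self.reduction_ratio})"
            )
        return self


class EdgeAttentionFusion(nn.Module):
    """Edge-attention skip refinement block; C channels in, C channels out."""

    def __init__(self, channels: int, reduction_ratio: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = EafConfig(channels, reduction_ratio).validate()
        self.config = cfg
        c, r = cfg.channels, cfg.reduction_ratio
        self.edge_conv = nn.DepthwiseConv2d(c, 3, rng=rng)
        self.squeeze = nn.Conv2d(c, c // r, 1, rng=rng)
        self.restore = nn.Conv2d(c // r, c, 1, rng=rng)
        self.fuse = nn.Conv2d(2 * c, c, 1, rng=rng)
        self.fuse_bn = nn.BatchNorm2d(c)
        self.refine = nn.DepthwiseConv2d(c, 3, rng=rng)
        self.refine_bn = nn.BatchNorm2d(c)

    def attention(self, x):
        """Edge-attention weights S2, strictly inside (0, 1)."""
        s1 = self.edge_conv(x)
        return F.sigmoid(self.restore(F.gelu(self.squeeze(s1))))

    def forward(self, x):
        s2 = self.attention(x)
        weighted = F.mul(x, s2)
        s = F.gelu(self.fuse_bn(self.fuse(F.concat([x, weighted], axis=1))))
        return F.gelu(self.refine_bn(self.refine(s)))


def eaf_forward(features: np.ndarray, config: EafConfig, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialised edge-attention block to a [C,H,W] array."""
    config.validate()
    arr = np.asarray(features, dtype=np.float32)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in input feature map")
    batched = arr.ndim == 4
    if not batched:
        arr = arr[None]
    if arr.shape[1] != config.channels:
        raise ConfigError(f"input has {arr.shape[1]} channels, config expects {config.channels}")
    block = EdgeAttentionFusion(config.channels, config.reduction_ratio,
                                rng=np.random.default_rng(seed)).eval()
    out = block(F.Tensor(arr)).data
    return out if batched else out[0]
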