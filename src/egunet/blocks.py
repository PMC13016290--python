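"""Decoder building blocks: shuffle upsampling, multi-scale gating, channel
attention modulation, and the gated fusion of the two attention branches.

The decoder restores resolution with CSU blocks (bilinear x2 upsample, 9x9
depthwise-separable conv, batch norm, channel shuffle, ReLU). At selected
stages a pair of complementary attention blocks refines the skip-fused
feature:

* ``MsagBlock`` - multi-scale spatial attention gating. Global (skip) and
  local (decoder) features pass through multi-scale convolution blocks, are
  summed and projected, and drive two parallel gates - sigmoid (retention)
  and tanh (signed modulation) - applied to a 1x1-projected copy of the
  local feature.
* ``CamBlock`` - channel attention modulation in the ConvNeXt mould: 3x3
  depthwise conv, group norm, an inverted-bottleneck channel MLP (C -> 4C
  -> C), squeeze-and-excitation reweighting, LayerScale and an optional
  stochastic-depth residual.

``fuse_branches`` combines the two branch outputs; the default strategy is
a gated weighted sum with elementwise convex weight sigmoid(Y_msag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as F
from . import nn
from ._tensor import ShapeRef, Tensor
from .errors import ConfigError, ShapeError

__all__ = [
    "FUSION_STRATEGIES", "MsagConfig", "CamConfig",
    "shuffle_permutation", "channel_shuffle", "CSUBlock",
    "MultiScaleConvBlock", "DualGate", "MsagBlock", "CamBlock",
    "fuse_branches",
]

FUSION_STRATEGIES = ("gated_weighted_sum", "cascade", "addition", "concatenation",
                     "multiplication")


@dataclass(frozen=True)
class MsagConfig:
    global_channels: int
    local_channels: int
    intermediate_channels: int | None = None  # default local_channels // 2

    @property
    def c_int(self) -> int:
        if self.intermediate_channels is not None:
            return self.intermediate_channels
        return max(self.local_channels // 2, 1)

    def validate(self) -> "MsagConfig":
        if self.global_channels < 1 or self.local_channels < 1 or self.c_int < 1:
            raise ConfigError("MSAG channel counts must be positive")
        return self


@dataclass(frozen=True)
class CamConfig:
    channels: int
    dw_kernel: int = 3
    mlp_expansion: int = 4
    se_reduction: int = 16
    layerscale_init: float = 1e-6
    droppath_rate: float = 0.0
    gn_groups: int = 8

    def validate(self) -> "CamConfig":
        if self.dw_kernel not in (3, 5, 7):
            raise ConfigError(f"CAM depthwise kernel must be 3, 5 or 7, got {self.dw_kernel}")
        if self.channels % self.gn_groups:
            raise ConfigError(
                f"CAM channels ({self.channels}) must be divisible by group-norm "
                f"groups ({self.gn_groups})"
            )
        if not 0.0 <= self.droppath_rate <= 1.0:
            raise ConfigError("droppath rate must lie in [0, 1]")
        return self


# ---------------------------------------------------------------------------
# channel shuffle + CSU


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """Index permutation of the ShuffleNet channel shuffle.

    Equivalent to reshape (g, C/g) -> transpose -> flatten; with C=4, g=2 the
    channel order (0,1,2,3) becomes (0,2,1,3).
    """
    if channels % groups:
        raise ConfigError(f"channels ({channels}) not divisible by shuffle groups ({groups})")
    return np.arange(channels).reshape(groups, channels // groups).T.reshape(-1)


def channel_shuffle(x, groups: int):
    c = x.shape[1]
    return F.take_channels(x, shuffle_permutation(c, groups))


class CSUBlock(nn.Module):
    """Channel-shuffle upsampling: ReLU(CS(BN(DSConv9x9(up(d; 2))))).

    Doubles spatial size; DSConv is a depthwise 9x9 (padding 4) followed by a
    pointwise 1x1 mapping C -> C_out. Output is non-negative (post-ReLU).
    """

    def __init__(self, in_channels: int, out_channels: int, shuffle_groups: int = 4,
                 kernel_size: int = 9, rng: np.random.Generator | None = None):
        super().__init__()
        if out_channels % shuffle_groups:
            raise ConfigError(
                f"CSU output channels ({out_channels}) not divisible by shuffle "
                f"groups ({shuffle_groups})"
            )
        self.depthwise = nn.DepthwiseConv2d(in_channels, kernel_size, rng=rng)
        self.pointwise = nn.Conv2d(in_channels, out_channels, 1, rng=rng)
        self.bn = nn.BatchNorm2d(out_channels)
        self.groups = shuffle_groups

    def forward(self, x):
        y = F.upsample_bilinear(x, 2)
        y = self.bn(self.pointwise(self.depthwise(y)))
        return F.relu(channel_shuffle(y, self.groups))


# ---------------------------------------------------------------------------
# MSAG branch


class MultiScaleConvBlock(nn.Module):
    """MCB: pointwise projection to C_int, then parallel depthwise convs at
    several kernel scales whose outputs are summed, then BN + GELU.

    ``multi_scale=False`` keeps only the pointwise projection (the MCB-off
    ablation of the spatial gate)."""

    def __init__(self, in_channels: int, c_int: int, kernels: tuple[int, ...] = (1, 3, 5),
                 multi_scale: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if not kernels:
            raise ConfigError("MCB needs at least one kernel scale")
        self.project = nn.Conv2d(in_channels, c_int, 1, rng=rng)
        self.kernels = tuple(kernels) if multi_scale else ()
        for k in self.kernels:
            setattr(self, f"dw{k}", nn.DepthwiseConv2d(c_int, k, rng=rng))
        self.bn = nn.BatchNorm2d(c_int)
        self.multi_scale = multi_scale

    def forward(self, x):
        p = self.project(x)
        if self.kernels:
            y = None
            for k in self.kernels:
                branch = getattr(self, f"dw{k}")(p)
                y = branch if y is None else F.add(y, branch)
        else:
            y = p
        return F.gelu(self.bn(y))


class DualGate(nn.Module):
    """Two parallel 1x1-conv gates: sigmoid retention A in (0,1), tanh signed
    modulation M in (-1,1); independent weights per branch."""

    def __init__(self, c_int: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.gate_a = nn.Conv2d(c_int, c_int, 1, rng=rng)
        self.gate_m = nn.Conv2d(c_int, c_int, 1, rng=rng)

    def forward(self, x):
        return F.sigmoid(self.gate_a(x)), F.tanh(self.gate_m(x))


class MsagBlock(nn.Module):
    """Multi-scale spatial attention gate.

    forward(g, x): f = GELU(BN(Conv1x1(MCB(g) + MCB(x)))); (A, M) = gates(f);
    x_lat = BN(Conv1x1(x)); Y = x_lat*A + x_lat*M; output = BN(Conv1x1(Y))
    back at x's channel count. ``use_dual_gate`` / ``use_gft`` expose the
    component ablations (single sigmoid gate; gating skipped entirely).
    """

    def __init__(self, global_channels: int, local_channels: int,
                 c_int: int | None = None, mcb_kernels: tuple[int, ...] = (1, 3, 5),
                 use_mcb: bool = True, use_dual_gate: bool = True, use_gft: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = MsagConfig(global_channels, local_channels, c_int).validate()
        self.config = cfg
        n = cfg.c_int
        self.mcb_g = MultiScaleConvBlock(global_channels, n, mcb_kernels, use_mcb, rng=rng)
        self.mcb_x = MultiScaleConvBlock(local_channels, n, mcb_kernels, use_mcb, rng=rng)
        self.fuse = nn.Conv2d(n, n, 1, rng=rng)
        self.fuse_bn = nn.BatchNorm2d(n)
        self.use_gft = use_gft
        self.use_dual_gate = use_dual_gate
        if use_gft:
            if use_dual_gate:
                self.gates = DualGate(n, rng=rng)
            else:
                self.gate_a = nn.Conv2d(n, n, 1, rng=rng)
        self.lat = nn.Conv2d(local_channels, n, 1, rng=rng)
        self.lat_bn = nn.BatchNorm2d(n)
        self.out = nn.Conv2d(n, local_channels, 1, rng=rng)
        self.out_bn = nn.BatchNorm2d(local_channels)

    def forward(self, g, x, forced_gates=None):
        if g.shape[-2:] != x.shape[-2:]:
            raise ShapeError(f"global/local spatial mismatch: {g.shape[-2:]} vs {x.shape[-2:]}")
        f = F.gelu(self.fuse_bn(self.fuse(F.add(self.mcb_g(g), self.mcb_x(x)))))
        if self.use_gft:
            x_lat = self.lat_bn(self.lat(x))
            if forced_gates is not None:
                a, m = forced_gates
                a = a if isinstance(a, (Tensor, ShapeRef)) else Tensor(np.asarray(a, dtype=np.float32))
                m = m if isinstance(m, (Tensor, ShapeRef)) else Tensor(np.asarray(m, dtype=np.float32))
            elif self.use_dual_gate:
                a, m = self.gates(f)
            else:
                a, m = F.sigmoid(self.gate_a(f)), None
            y = F.mul(x_lat, a)
            if m is not None:
                y = F.add(y, F.mul(x_lat, m))
        else:
            y = f
        return self.out_bn(self.out(y))


# ---------------------------------------------------------------------------
# CAM branch


class CamBlock(nn.Module):
    """Channel attention modulation block (ConvNeXt-style residual).

    y = x + DropPath(gamma * SE(Conv2(GELU(Conv1(GN(DWConv(x))))))) with
    Conv1: C->4C, Conv2: 4C->C. With gamma initialised to 0 the block is an
    exact identity, which the tests exploit.
    """

    def __init__(self, channels: int, dw_kernel: int = 3, mlp_expansion: int = 4,
                 se_reduction: int = 16, layerscale_init: float = 1e-6,
                 droppath_rate: float = 0.0, gn_groups: int = 8,
                 rng: np.random.Generator | None = None,
                 droppath_rng: np.random.Generator | None = None):
        super().__init__()
        cfg = CamConfig(channels, dw_kernel, mlp_expansion, se_reduction,
                        layerscale_init, droppath_rate, gn_groups).validate()
        self.config = cfg
        c = channels
        hidden = mlp_expansion * c
        se_hidden = max(c // se_reduction, 1)
        self.dw = nn.DepthwiseConv2d(c, dw_kernel, rng=rng)
        self.gn = nn.GroupNorm(gn_groups, c)
        self.mlp1 = nn.Conv2d(c, hidden, 1, rng=rng)
        self.mlp2 = nn.Conv2d(hidden, c, 1, rng=rng)
        self.se_fc1 = nn.Conv2d(c, se_hidden, 1, rng=rng)
        self.se_fc2 = nn.Conv2d(se_hidden, c, 1, rng=rng)
        self.gamma = nn.Parameter(np.full(c, layerscale_init, dtype=np.float32))
        self.droppath = nn.DropPath(droppath_rate, rng=droppath_rng)

    def se_scale(self, z):
        """Squeeze-and-excitation channel weights in (0,1)^C."""
        return F.sigmoid(self.se_fc2(F.relu(self.se_fc1(F.global_avg_pool(z)))))

    def forward(self, x):
        z = self.mlp2(F.gelu(self.mlp1(self.gn(self.dw(x)))))
        z = F.mul(z, self.se_scale(z))
        if isinstance(x, ShapeRef):
            return x
        z = F.mul(z, self._gamma_view())
        return F.add(x, self.droppath(z))

    def _gamma_view(self):
        g = self.gamma
        return F.reshape(g, (1, g.shape[0], 1, 1))


# ---------------------------------------------------------------------------
# branch fusion


def fuse_branches(y_msag, y_cam, strategy: str = "gated_weighted_sum",
                  concat_proj: nn.Conv2d | None = None):
    """Combine the spatial-gate and channel-attention branch outputs.

    gated_weighted_sum: Out = s*Y_msag + (1-s)*Y_cam with s = sigmoid(Y_msag),
    an elementwise convex combination (Out always lies between the branches).
    addition / multiplication are elementwise; concatenation needs a 1x1
    projection module (2C -> C). The cascade strategy is sequential and is
    handled by the decoder stage (CAM applied to the MSAG output), not here.
    """
    if strategy not in FUSION_STRATEGIES:
        raise ConfigError(f"unknown fusion strategy {strategy!r}; options: {FUSION_STRATEGIES}")
    if strategy == "cascade":
        raise ConfigError("cascade fusion is sequential; apply the CAM block to the MSAG output")
    if not isinstance(y_msag, ShapeRef) and y_msag.shape != y_cam.shape:
        raise ShapeError(f"branch shape mismatch: {y_msag.shape} vs {y_cam.shape}")
    if strategy == "gated_weighted_sum":
        s = F.sigmoid(y_msag)
        one_minus = F.add(F.mul(s, -1.0), 1.0)
        return F.add(F.mul(s, y_msag), F.mul(one_minus, y_cam))
    if strategy == "addition":
        return F.add(y_msag, y_cam)
    if strategy == "multiplication":
        return F.mul(y_msag, y_cam)
    # concatenation
    if concat_proj is None:
        raise ConfigError("concatenation fusion requires the 1x1 projection module")
    return concat_proj(F.concat([y_msag, y_cam], axis=1))
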