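"""Full encoder-decoder segmentation network with budget accounting.

Architecture. The encoder produces E1..E4 at H/2..H/16. The decoder runs
four stages, deepest first:

* D4: the first CSU block upsamples E4 from H/16 to H/8 (no skip here).
* D3: fuses skip E3 at H/8, then CSU to H/4.
* D2: fuses skip E2 at H/4, then CSU to H/2.
* D1: fuses skip E1 at H/2, then CSU to H.

A 1x1 head maps the final feature to K class logits at input resolution.
Each skip is optionally refined by an edge-attention block, then projected
by a 1x1 conv and added to the decoder feature (the plain baseline fusion).
Stages listed in ``attention_stages`` additionally apply the spatial-gate /
channel-attention pair to the skip-fused feature and combine the branches
with the configured fusion strategy. This stage layout (attention running at
the pre-upsample resolution of each skip, D4 skipless) is what makes the
module parameter/FLOP costs land in the regime the budget ablations report;
see docs/methods.md for the derivation.

Budgets. ``count_budget`` reports trainable parameters and conv
multiply-accumulates (MACs) from a shape-only forward pass at a stated input
size. ``flops`` is recorded under the 2xMAC convention alongside the raw MAC
count; published "GFLOPs" figures for segmentation models almost always
equal MACs (thop/ptflops convention), so comparisons against such figures
should use the ``macs`` field. Counting is additive by construction: every
module's cost is independent of which other modules are enabled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import _tensor as F
from . import nn
from ._tensor import MacCounter, ShapeRef, Tensor
from .backbone import BackboneConfig, ConvBackbone
from .blocks import FUSION_STRATEGIES, CamBlock, CSUBlock, MsagBlock, fuse_branches
from .eaf import EdgeAttentionFusion
from .errors import ConfigError, ShapeError

__all__ = ["ModelConfig", "SegmentationNet", "build_model", "BudgetReport", "count_budget"]

STAGE_NAMES = ("D4", "D3", "D2", "D1")  # deepest (H/16 input) to shallowest
_SKIP_OF_STAGE = {"D3": 2, "D2": 1, "D1": 0}  # stage -> encoder stage index (E3, E2, E1)


@dataclass(frozen=True)
class ModelConfig:
    """Everything that defines the architecture.

    ``decoder_channels`` are the widths after each stage's upsample, deepest
    first: (H/8, H/4, H/2, H). ``attention_stages`` selects where the
    spatial/channel attention pair runs (D4 has no skip and is rejected).
    ``eaf_per_skip`` toggles edge attention per skip (E1, E2, E3) and
    supports the 0/1/2/3-module ablation.
    """

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    num_classes: int = 9
    decoder_channels: tuple[int, int, int, int] = (128, 64, 32, 16)
    msag_enabled: bool = True
    cam_enabled: bool = True
    eaf_enabled: bool = True
    eaf_per_skip: tuple[bool, bool, bool] = (True, True, True)
    eaf_reduction: int = 4
    attention_stages: tuple[str, ...] = ("D3", "D2")
    fusion_strategy: str = "gated_weighted_sum"
    c_int_ratio: float = 0.5
    mcb_kernels: tuple[int, ...] = (1, 3, 5)
    cam_kernel: int = 3
    se_reduction: int = 16
    layerscale_init: float = 1e-6
    droppath_rate: float = 0.0
    gn_groups: int = 8
    shuffle_groups: int = 4
    msag_use_mcb: bool = True
    msag_use_dual_gate: bool = True
    msag_use_gft: bool = True

    def validate(self) -> "ModelConfig":
        self.backbone.validate()
        if self.num_classes < 2:
            raise ConfigError("need at least 2 classes (background + foreground)")
        if len(self.decoder_channels) != 4 or any(c < 1 for c in self.decoder_channels):
            raise ConfigError("decoder_channels must be 4 positive counts")
        if self.fusion_strategy not in FUSION_STRATEGIES:
            raise ConfigError(
                f"unknown fusion strategy {self.fusion_strategy!r}; options: {FUSION_STRATEGIES}")
        for s in self.attention_stages:
            if s not in STAGE_NAMES:
                raise ConfigError(f"unknown decoder stage {s!r}; stages are {STAGE_NAMES}")
            if s == "D4":
                raise ConfigError(
                    "attention fusion needs a skip connection for its global input; "
                    "stage D4 consumes E4 directly and has none")
        if (self.msag_enabled or self.cam_enabled) and not self.attention_stages:
            raise ConfigError("attention blocks enabled but attention_stages is empty")
        if not 0 < self.c_int_ratio <= 1:
            raise ConfigError("c_int_ratio must be in (0, 1]")
        return self

    # channel bookkeeping -----------------------------------------------------
    def stage_io(self) -> dict[str, tuple[int, int]]:
        """Map stage name -> (input channels at skip resolution, CSU output channels)."""
        c4 = self.backbone.stage_channels[3]
        d = self.decoder_channels
        return {"D4": (c4, d[0]), "D3": (d[0], d[1]), "D2": (d[1], d[2]), "D1": (d[2], d[3])}


class DecoderStage(nn.Module):
    """One decoder stage: optional skip fusion (plain or attention-gated),
    then channel-shuffle upsampling."""

    def __init__(self, name: str, config: ModelConfig, rng, droppath_rng=None):
        super().__init__()
        self.name = name
        self.strategy = config.fusion_strategy
        x_ch, out_ch = config.stage_io()[name]
        self.skip_index = _SKIP_OF_STAGE.get(name)
        if self.skip_index is not None:
            skip_ch = config.backbone.stage_channels[self.skip_index]
            if config.eaf_enabled and config.eaf_per_skip[self.skip_index]:
                self.eaf = EdgeAttentionFusion(skip_ch, config.eaf_reduction, rng=rng)
            self.proj = nn.Conv2d(skip_ch, x_ch, 1, rng=rng)
            if name in config.attention_stages:
                c_int = max(int(round(x_ch * config.c_int_ratio)), 1)
                if config.msag_enabled:
                    self.msag = MsagBlock(
                        skip_ch, x_ch, c_int, config.mcb_kernels,
                        use_mcb=config.msag_use_mcb,
                        use_dual_gate=config.msag_use_dual_gate,
                        use_gft=config.msag_use_gft, rng=rng)
                if config.cam_enabled:
                    self.cam = CamBlock(
                        x_ch, config.cam_kernel, 4, config.se_reduction,
                        config.layerscale_init, config.droppath_rate,
                        config.gn_groups, rng=rng, droppath_rng=droppath_rng)
                if (config.msag_enabled and config.cam_enabled
                        and self.strategy == "concatenation"):
                    self.concat_proj = nn.Conv2d(2 * x_ch, x_ch, 1, rng=rng)
        self.csu = CSUBlock(x_ch, out_ch, config.shuffle_groups, rng=rng)

    def forward(self, x, skip=None):
        if self.skip_index is not None and skip is not None:
            if skip.shape[-2:] != x.shape[-2:]:
                raise ShapeError(
                    f"stage {self.name}: skip at {skip.shape[-2:]} does not match "
                    f"decoder feature at {x.shape[-2:]}")
            refined = self.eaf(skip) if hasattr(self, "eaf") else skip
            x = F.add(x, self.proj(refined))
            has_msag, has_cam = hasattr(self, "msag"), hasattr(self, "cam")
            if has_msag and has_cam:
                y_msag = self.msag(refined, x)
                if self.strategy == "cascade":
                    x = self.cam(y_msag)
                else:
                    y_cam = self.cam(x)
                    x = fuse_branches(y_msag, y_cam, self.strategy,
                                      getattr(self, "concat_proj", None))
            elif has_msag:
                x = self.msag(refined, x)
            elif has_cam:
                x = self.cam(x)
        return self.csu(x)


class SegmentationNet(nn.Module):
    """Encoder + edge-refined skips + attention-gated decoder + 1x1 head."""

    def __init__(self, config: ModelConfig, seed: int | None = 0):
        super().__init__()
        config.validate()
        self.config = config
        if seed is None:  # zero-initialised; enough for shape passes and budget counting
            rng = None
            self.droppath_rng = None
        else:
            rng = np.random.default_rng(seed)
            self.droppath_rng = np.random.default_rng(rng.integers(2**31))
        self.backbone = ConvBackbone(config.backbone, rng=rng)
        for name in STAGE_NAMES:
            setattr(self, name, DecoderStage(name, config, rng, self.droppath_rng))
        self.head = nn.Conv2d(config.decoder_channels[3], config.num_classes, 1, rng=rng)

    def forward(self, x):
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        feats = self.backbone(x)
        cur = self.D4(feats[3])
        cur = self.D3(cur, feats[2])
        cur = self.D2(cur, feats[1])
        cur = self.D1(cur, feats[0])
        return self.head(cur)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a [N,C,H,W] batch (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            logits = self(Tensor(np.asarray(images, dtype=np.float32)))
            return F.softmax(logits, axis=1).data
        finally:
            self.train(was_training)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(images), axis=1)


def build_model(config: ModelConfig, seed: int = 0) -> SegmentationNet:
    return SegmentationNet(config, seed=seed)


# ---------------------------------------------------------------------------
# budget accounting


@dataclass
class BudgetReport:
    """Parameter and MAC/FLOP totals with a per-module breakdown.

    ``flops`` follows the 2xMAC convention; ``macs`` is the raw
    multiply-accumulate count (what thop-style "GFLOPs" figures report).
    Breakdown entries sum to the totals.
    """

    trainable_params: int
    macs: int
    input_size: tuple[int, int, int]
    per_module: dict[str, tuple[int, int]]  # name -> (params, macs)
    convention: str = ("macs = conv/linear multiply-accumulates at the stated input size; "
                       "flops = 2 * macs")

    @property
    def flops(self) -> int:
        return 2 * self.macs

    def to_dict(self) -> dict:
        return {
            "trainable_params": self.trainable_params,
            "params_millions": round(self.trainable_params / 1e6, 4),
            "macs": self.macs,
            "macs_giga": round(self.macs / 1e9, 4),
            "flops_2xmac": self.flops,
            "input_size": list(self.input_size),
            "convention": self.convention,
            "per_module": {k: {"params": p, "macs": m} for k, (p, m) in self.per_module.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _group_scope(scope: str) -> str:
    parts = scope.replace(".", "/").split("/")
    if parts and parts[0] in ("SegmentationNet", "<root>"):
        parts = parts[1:]
    if not parts or parts[0] in ("weight", "bias"):
        return "head"
    if parts[0] == "backbone":
        return "backbone"
    if parts[0] in STAGE_NAMES:
        return "/".join(parts[:2]) if len(parts) > 1 else parts[0]
    return parts[0]


def count_budget(model: SegmentationNet, input_size: tuple[int, int, int] = (1, 224, 224)
                 ) -> BudgetReport:
    """Count trainable parameters and conv MACs at a fixed input size.

    MACs come from a shape-only forward pass (no arithmetic on real data),
    so this is fast even for reference-scale configurations, and deterministic.
    """
    c, h, w = input_size
    with MacCounter() as counter:
        model(ShapeRef((1, c, h, w)))
    macs_by_group: dict[str, int] = {}
    for scope, m in counter.macs_by_scope.items():
        g = _group_scope(scope)
        macs_by_group[g] = macs_by_group.get(g, 0) + m
    params_by_group: dict[str, int] = {}
    for name, p in model.named_parameters():
        g = _group_scope(name)
        params_by_group[g] = params_by_group.get(g, 0) + p.data.size
    groups = sorted(set(macs_by_group) | set(params_by_group))
    per_module = {g: (params_by_group.get(g, 0), macs_by_group.get(g, 0)) for g in groups}
    total_p = sum(p for p, _ in per_module.values())
    total_m = sum(m for _, m in per_module.values())
    assert total_p == model.num_parameters()
    return BudgetReport(total_p, total_m, input_size, per_module)


def budget_for_config(config: ModelConfig, input_size=(1, 224, 224)) -> BudgetReport:
    """Budget of a configuration without materialising trained weights
    (parameters are allocated zero-initialised)."""
    return count_budget(SegmentationNet(config.validate(), seed=None), input_size)


def module_deltas(config: ModelConfig, input_size=(1, 224, 224)) -> dict[str, dict[str, float]]:
    """Parameter/MAC increments of each module over the plain baseline.

    Returns per-module deltas (millions of parameters / GMACs) for the edge
    attention (eaf), channel attention (cam) and spatial gate (msag) toggles,
    plus the all-modules-on increment and the base/full totals.
    """
    base_cfg = replace(config, msag_enabled=False, cam_enabled=False, eaf_enabled=False)
    full = budget_for_config(config, input_size)
    base = budget_for_config(base_cfg, input_size)
    eaf_only = budget_for_config(replace(base_cfg, eaf_enabled=True), input_size)
    cam_on = budget_for_config(replace(base_cfg, eaf_enabled=True, cam_enabled=True), input_size)
    msag_on = budget_for_config(replace(base_cfg, eaf_enabled=True, msag_enabled=True), input_size)

    def d(a: BudgetReport, b: BudgetReport) -> dict[str, float]:
        return {"params_m": (a.trainable_params - b.trainable_params) / 1e6,
                "gmacs": (a.macs - b.macs) / 1e9}

    return {
        "eaf": d(eaf_only, base),
        "cam": d(cam_on, eaf_only),
        "msag": d(msag_on, eaf_only),
        "all_modules": d(full, base),
        "base_total": {"params_m": base.trainable_params / 1e6, "gmacs": base.macs / 1e9},
        "full_total": {"params_m": full.trainable_params / 1e6, "gmacs": full.macs / 1e9},
    }
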