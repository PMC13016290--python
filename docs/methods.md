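# Methods

## The model

`egunet` implements a 2D encoder–decoder segmentation network for
single-channel medical image slices whose decoder is built around two ideas:

1. **Edge-refined skip connections.** Each encoder feature routed through a
   skip connection first passes an *edge attention fusion* (EAF) block: a
   learned 3×3 depthwise convolution acts as a high-pass filter producing an
   edge response `S1`; a squeeze/restore pair of 1×1 convolutions
   (`C → C/r → C`, GELU between, sigmoid after) turns it into elementwise
   attention weights `S2 ∈ (0,1)`; the original feature and its weighted copy
   `F ⊙ S2` are concatenated and compressed back to `C` channels
   (1×1 conv + BN + GELU); a final depthwise 3×3 + BN + GELU refines the
   result. The reduction ratio defaults to `r = 4`. Each skip has its own
   independently-weighted block (weights are not shared across scales).

2. **Gated dual-attention fusion in the decoder.** At selected decoder
   stages, the skip-fused feature `x` is processed by two parallel branches:

   * a **multi-scale spatial attention gate** (MSAG): the skip feature `g`
     (global guidance) and `x` each pass a multi-scale convolution block
     (MCB: 1×1 projection to `C_int` followed by parallel depthwise
     convolutions at kernel sizes {1,3,5} whose outputs are summed, then
     BN + GELU); the sum is projected (1×1 + BN + GELU) into a shared feature
     `F`, from which two independent 1×1-conv gates produce
     `A = σ(Conv(F)) ∈ (0,1)` and `M = tanh(Conv(F)) ∈ (−1,1)`. A lateral
     projection `x_lat = BN(Conv1×1(x))` is modulated as
     `Y = x_lat ⊙ A + x_lat ⊙ M` and projected back to `x`'s width
     (1×1 + BN). `C_int = C_x/2` by default.
   * a **channel attention modulation** block (CAM), a ConvNeXt-style
     residual: `x + DropPath(γ ⊙ SE(Conv₂(GELU(Conv₁(GN(DWConv3×3(x)))))))`
     with `Conv₁: C → 4C`, `Conv₂: 4C → C`, squeeze-and-excitation
     reweighting of the MLP output (bottleneck `C/16`, sigmoid scale),
     LayerScale `γ` initialised at 1e−6 and stochastic depth disabled by
     default (rate 0, so the block is deterministic in training too).

   The branches are combined by **gated weighted summation**:
   `Out = ∂ ⊙ Y_MSAG + (1−∂) ⊙ Y_CAM` with `∂ = σ(Y_MSAG)` elementwise — a
   convex combination, so the output is always between the branch outputs.
   Four ablation strategies are selectable: addition, multiplication,
   1×1-projected concatenation, and cascade (CAM applied to the MSAG output).

Resolution is restored by **channel-shuffle upsampling** (CSU) blocks:
bilinear ×2 upsample, 9×9 depthwise + 1×1 pointwise convolution, batch norm,
channel shuffle (groups default 4), ReLU.

### Stage layout

The encoder produces stages E1..E4 at `H/2 .. H/16` (a strided stem plus
three strided transitions; the packaged reference backbone is a plain CNN —
two-ish 3×3 conv+BN+GELU blocks per stage — behind a pluggable interface,
since token-mixing encoders are out of scope here). The decoder runs four
stages deepest-first:

| stage | operates at | skip | then |
|-------|-------------|------|------|
| D4 | H/16 | — (consumes E4 directly) | CSU → H/8 |
| D3 | H/8 | E3 | fuse, CSU → H/4 |
| D2 | H/4 | E2 | fuse, CSU → H/2 |
| D1 | H/2 | E1 | fuse, CSU → H |

followed by a 1×1 head to K class logits at input resolution. Skip fusion at
every stage starts from 1×1-projected elementwise addition (the plain
baseline); stages in `attention_stages` (default `{D3, D2}`) additionally
apply the MSAG/CAM pair as above, with `g` the (optionally edge-refined)
skip and `x` the skip-fused decoder feature. D4 has no skip, so requesting
attention there is a configuration error.

This particular assignment — attention running at the *pre-upsample*
resolution of each stage, the deepest stage skipless — was chosen because it
is the only stage geometry whose per-module parameter and FLOP increments
can land in the regime of the reference budget figures this implementation
is calibrated against: at post-upsample resolutions the minimum attainable
MACs-per-parameter ratio of the CAM/MSAG blocks exceeds what those figures
imply (by ~40%), at pre-upsample resolutions an exact integer solution
exists. The derivation lives in `egunet.calibration`.

## Budget accounting and calibration

`count_budget` counts trainable parameters (including biases and norm
affines) and convolution multiply–accumulates (MACs) from a shape-only
instrumented forward pass at a stated input size, with a per-block
breakdown. Two FLOP conventions coexist in the literature; the report
carries both numbers: `flops = 2×MACs`, and the raw `macs` field, which is
what thop/ptflops-style "GFLOPs" figures in segmentation papers report.
Comparisons against such printed figures use the MAC field.

Counting is **additive by construction**: a module's cost is independent of
which other modules are enabled (this is a tested invariant). The
calibration search (`scripts/calibrate_budget.py`) recovers integer channel
widths such that, at 224×224:

* the three EAF blocks add ≈ 0.33 M parameters / 0.72 G,
* the two CAM blocks ≈ 0.06 M / 0.13 G,
* the two MSAG blocks ≈ 0.04 M / 0.07 G,
* and the module-free baseline totals ≈ 17.07 M / 9.90 G,

all at printed 2-decimal rounding. The frozen result is skip widths
(88, 188, 288), deep width 796 with stage depths (3, 1, 3, 2), and decoder
widths (60, 64, 100, 36) deepest-first, with 4 group-norm groups (4 rather
than 8 because decoder widths must be divisible by the group count, and no
multiple-of-8 layout lands the CAM increment at printed rounding).

**Known inconsistency.** The reference figures also quote a combined
all-modules increment of ≈ +0.45 M / +1.5 G and a full-model total of
17.52 M / 11.40 G, which exceed the sum of the individually quoted
increments (0.43 M / 0.92 G; the gated fusion itself has no parameters and
negligible elementwise cost). No additive accounting can reproduce both the
per-module rows and the combined row; this implementation reproduces the
per-module rows and the base totals, and reports the combined figures as
computed (0.43 M / 0.91 G; full total 17.50 M / 10.81 G). The two
corresponding acceptance assertions are expected to fail and are annotated
accordingly in the test suite.

## Evaluation metrics

* **DSC** = 2|Mp ∩ Mg| / (|Mp| + |Mg|), symmetric, in [0,1]. Conventions
  for degenerate masks (not fixed by the defining formula): both empty → 1.0;
  exactly one empty → 0.0.
* **HD95** = max(d95(R1,R2), d95(R2,R1)) where R1, R2 are boundary point
  sets (foreground voxels with a face-adjacent background neighbour:
  4-connectivity in 2D, 6 in 3D) and d95 the 95th percentile (linear
  interpolation between order statistics) of directed nearest-neighbour
  Euclidean distances, computed via the spacing-aware distance transform.
  Results are in millimetres when a voxel spacing is given, voxels
  otherwise. If either mask is empty the value is *undefined* (NaN), not 0,
  and such records are excluded from aggregation with a logged count.
* **Aggregation**: mean over cases per class, then mean over classes.
  Evaluation is per reassembled case (stacked slices scored as one 3D
  volume) by default, with a per-slice mode behind a flag.
* **Paired comparison**: two-sided Wilcoxon signed-rank on per-case
  differences, zero differences dropped (classical policy, count reported),
  exact null for n ≤ 25 and normal approximation above (via
  `scipy.stats.wilcoxon`, cross-checked in the tests against full
  sign-assignment enumeration); percentile-bootstrap 95% CI of the mean
  with 1000 resamples, seed-deterministic.

## Training protocol

* Loss: `α·CE + β·softDice` on softmax probabilities; soft Dice averages
  over **all** classes including background, smoothing ε = 1e−5; defaults
  α = β = 0.5 (a 0.3/0.7 weighting suits cardiac-MR-like tasks).
* Optimiser: AdamW (β = 0.9/0.999, weight decay 1e−4) with cosine-annealed
  learning rate from `base_lr` to 0 over the epoch budget; batch size 24;
  fixed seed 1234 throughout.
* Augmentation (online, per sample): with p = 0.5 a right-angle transform —
  uniform k·90° rotation plus, with a fair coin, a flip along one uniformly
  chosen axis (one defensible reading of "random horizontal or vertical
  flips"; alternatives are a policy parameter away); otherwise with
  conditional p = 0.25 a continuous rotation uniform in [−20°, +20°]
  (bilinear image, nearest label); otherwise identity. Branch frequencies
  (0.5 / 0.125 / 0.375) are verified by a binomial test.
* Preprocessing: per-slice resize to the network input size; bicubic image
  interpolation for CT-like data, nearest for MR-like data, labels always
  nearest (so no new class ids can appear); edge-replicating borders keep
  constant images constant under the cubic spline.
* TTA: deterministic transform sets (2 passes: identity + horizontal flip;
  or 8: four right-angle rotations × two flips), fused by averaging in
  softmax-probability space (the fusion space is not dictated by the
  protocol; probability averaging keeps the output on the simplex) and
  renormalised.
* Checkpoint selection: best validation DSC, restored at the end of
  training.
* Determinism: single-device only. All randomness flows from the config
  seed through `numpy.random.Generator`; two runs with the same seed are
  bitwise identical (tested).

## Synthetic phantoms

The generator emulates the geometry regimes that drive segmentation
difficulty rather than imaging physics: a large elliptical "organ", a thin
annulus (thickness uniform 1–4 px — the thin-walled, low-contrast myocardium
failure mode, and a stress test for boundary-distance metrics), and a small
ellipse (a small organ that may be absent: each structure is dropped with
p = 0.05, so every class is present with probability ≥ 0.9). Class
intensities are evenly spaced over the contrast range (default [0.1, 0.9])
with additive Gaussian noise (default σ = 0.05; the spec validates a
≥ 2σ separation between adjacent class means so the task stays learnable);
later shapes are drawn on top, keeping classes disjoint; infeasible
geometry (sub-pixel ring, fully occluded structure) triggers a logged
regeneration. Pseudo-3D cases stack 8–16 slices whose shape parameters
drift linearly in z.

What passing the desk-scale tests does **not** show: robustness to scanner
noise distributions, intensity inhomogeneity, anatomical variability,
inter-rater label noise, or class imbalance at clinical scale. The phantom
task is intensity-separable by design; it validates the pipeline (shapes,
gradients, optimisation, metrics, reproducibility), not clinical accuracy.

## Problem sizes (desk scale)

The default study conditions are 64×64 four-class phantoms with a
400/50/50 train/val/test split. The default small model is a
(12, 24, 32, 48)-channel encoder with a (32, 24, 16, 12) decoder
(≈ 0.18 M parameters), trained 12 epochs at `base_lr` 5e−3 — on these
conditions it reaches ≈ 0.95–0.97 mean foreground DSC on the held-out split
in a few minutes on one CPU core. Unit tests use a still smaller
(4, 8, 8, 16) model on 32×32 inputs. The reference-scale calibrated
configuration (17.5 M parameters) is only ever run through the shape-mode
budget engine, never trained here.

## Numerical choices

* All network arithmetic in float32; statistics and metrics in float64.
* The numerical core is a small reverse-mode autodiff on numpy arrays
  written for this package (dense/depthwise conv via slice-accumulated
  im2col, batch/group norm with hand-derived backward, half-pixel bilinear
  resampling); every op is tested against central finite differences and
  conv forward against scipy.
* GELU is exact (erf), not the tanh approximation.
* Batch norm: per-channel over batch+space, momentum 0.1, running stats
  used in eval mode. Zero-initialised biases and shifts make the zero image
  a fixed point of conv/norm stacks (used as a test oracle).
* He-normal weight init; prediction ties broken by `argmax` (lowest class
  index wins).
* Open-interval gate assertions (σ, tanh strictly inside their codomains)
  are evaluated in float64 at moderate activation scales; float32 rounds
  σ(x) to exactly 1.0 for x ≳ 17.

## Known limitations

* The encoder is a plain CNN reference, not a token-mixing architecture;
  absolute benchmark accuracy on real datasets is out of scope.
* Budget non-additivity of the reference combined figures (above) is
  unresolvable within an additive accounting.
* MCB topology (shared 1×1 projection feeding parallel depthwise branches)
  and the gate source (post-BN MSAG output feeds the fusion gate ∂) are
  design choices where the written record underdetermines the block; both
  are config-exposed.
* No multi-worker or multi-device determinism guarantees; no 3D
  convolutions (volumes are handled slice-wise and restacked).
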