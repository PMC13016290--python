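"""Training protocol: hybrid loss, augmentation, preprocessing, schedule, TTA.

The loss is a weighted combination alpha*CE + beta*softDice of pixelwise
cross-entropy and soft Dice computed on softmax probabilities over all
classes (background included), with smoothing eps = 1e-5. Optimisation uses
AdamW with a cosine-annealed learning rate from ``base_lr`` to ``min_lr``
(default 0) over the epoch budget.

Online augmentation follows a two-branch policy: with probability 0.5 a
right-angle transform (uniform rot90 multiple plus a coin-flip flip along
one uniformly chosen axis); otherwise, with conditional probability 0.25, a
continuous rotation uniform in [-20, +20] degrees (bilinear for the image,
nearest for the label); otherwise identity. Branch frequencies are therefore
(0.5, 0.125, 0.375). Image and label always receive identical geometry.

Test-time augmentation is deterministic: ``flip`` mode averages 2 passes
(identity + horizontal flip), ``flip+rot90`` averages 8 (4 right-angle
rotations x 2 flips), fused in softmax-probability space and renormalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import _tensor as F
from ._tensor import Tensor
from .errors import ConfigError, ShapeError
from .model import SegmentationNet
from .optim import AdamW, cosine_lr
from .synthetic import SegmentationSample

__all__ = ["TrainConfig", "AugmentPolicy", "hybrid_loss", "augment", "preprocess",
           "tta_predict", "train", "TTA_MODES"]

logger = logging.getLogger(__name__)

TTA_MODES = {"flip": 2, "flip+rot90": 8}
DICE_EPS = 1e-5


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (defaults follow the abdominal-CT recipe:
    AdamW, cosine annealing to 0, batch 24, alpha = beta = 0.5, seed 1234)."""

    epochs: int = 30
    base_lr: float = 1e-3
    min_lr: float = 0.0
    batch_size: int = 24
    alpha: float = 0.5
    beta: float = 0.5
    weight_decay: float = 1e-4
    seed: int = 1234
    input_size: int = 224
    augment: bool = True
    val_every: int = 1

    def validate(self) -> "TrainConfig":
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("loss weights alpha and beta must be non-negative")
        if self.min_lr > self.base_lr:
            raise ConfigError("min_lr must not exceed base_lr")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")
        return self


@dataclass(frozen=True)
class AugmentPolicy:
    p_geo: float = 0.5
    p_small_rot: float = 0.25  # conditional on the first branch not firing
    max_angle: float = 20.0

    def validate(self) -> "AugmentPolicy":
        if not (0 <= self.p_geo <= 1 and 0 <= self.p_small_rot <= 1):
            raise ConfigError("augmentation probabilities must lie in [0, 1]")
        return self


# ---------------------------------------------------------------------------
# loss


def hybrid_loss(logits, labels, alpha: float = 0.5, beta: float = 0.5):
    """alpha*CE + beta*softDice on [N,K,H,W] logits and [N,H,W] int labels.

    Soft Dice is 1 - mean over classes of (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps)
    with sums over batch and space. Returns a scalar Tensor (autograd-ready).
    """
    if not isinstance(logits, Tensor):
        logits = Tensor(np.asarray(logits, dtype=np.float32))
    lab = np.asarray(labels)
    n, k = logits.shape[0], logits.shape[1]
    if lab.shape != (n,) + tuple(logits.shape[2:]):
        raise ShapeError(f"labels {lab.shape} do not match logits {logits.shape}")
    if lab.min() < 0 or lab.max() >= k:
        raise ValueError(f"label values must lie in 0..{k - 1}, got "
                         f"[{lab.min()}, {lab.max()}]")
    onehot = np.zeros(logits.shape, dtype=logits.dtype.type)
    np.put_along_axis(onehot, lab[:, None], 1.0, axis=1)
    onehot_t = Tensor(onehot)
    logp = F.log_softmax(logits, axis=1)
    ce = F.mul(F.reduce_mean(F.reduce_sum(F.mul(onehot_t, logp), axis=1)), -1.0)
    probs = F.exp(logp)
    inter = F.reduce_sum(F.mul(probs, onehot_t), axis=(0, 2, 3))
    sums = F.add(F.reduce_sum(probs, axis=(0, 2, 3)),
                 F.reduce_sum(onehot_t, axis=(0, 2, 3)))
    dice_per_class = F.mul(F.add(F.mul(inter, 2.0), DICE_EPS),
                           F.power(F.add(sums, DICE_EPS), -1.0))
    dice_loss = F.add(F.mul(F.reduce_mean(dice_per_class), -1.0), 1.0)
    return F.add(F.mul(ce, alpha), F.mul(dice_loss, beta))


# ---------------------------------------------------------------------------
# augmentation


def _apply_rightangle(img: np.ndarray, lab: np.ndarray, k: int, flip_axis: int | None):
    img = np.rot90(img, k, axes=(-2, -1))
    lab = np.rot90(lab, k, axes=(-2, -1))
    if flip_axis is not None:
        img = np.flip(img, axis=-1 if flip_axis else -2)
        lab = np.flip(lab, axis=-1 if flip_axis else -2)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def augment(sample: SegmentationSample, policy: AugmentPolicy,
            rng: np.random.Generator) -> SegmentationSample:
    """One stochastic draw of the augmentation policy; image and label share
    the same geometry; the branch taken is recorded in ``meta['augment']``."""
    policy.validate()
    img, lab = sample.image, sample.label
    if rng.random() < policy.p_geo:
        k = int(rng.integers(0, 4))
        axis = int(rng.integers(0, 2))  # 0: vertical flip, 1: horizontal flip
        do_flip = rng.random() < 0.5
        img, lab = _apply_rightangle(img, lab, k, axis if do_flip else None)
        branch = "rightangle"
    elif rng.random() < policy.p_small_rot:
        angle = float(rng.uniform(-policy.max_angle, policy.max_angle))
        img = np.stack([ndimage.rotate(c, angle, reshape=False, order=1,
                                       mode="nearest") for c in img])
        lab = ndimage.rotate(lab, angle, reshape=False, order=0, mode="nearest")
        branch = "small_rotation"
    else:
        branch = "identity"
    meta = dict(sample.meta)
    meta["augment"] = branch
    return SegmentationSample(img.astype(np.float32), lab.astype(sample.label.dtype),
                              sample.case_id, meta)


# ---------------------------------------------------------------------------
# preprocessing


_IMAGE_ORDERS = {"bicubic": 3, "nearest": 0}
DATASET_MODES = {"abdominal-ct": "bicubic", "cardiac-mr": "nearest"}


def preprocess(volume, labels, target_size: int = 224,
               image_interp: str = "bicubic", dataset_mode: str | None = None,
               case_id: str = "case") -> list[SegmentationSample]:
    """Slice a [Z,H,W] volume and resize each slice to ``target_size``.

    Image interpolation is bicubic or nearest (selectable directly or via
    ``dataset_mode``); label maps always use nearest-neighbour, so no new
    class ids can appear.
    """
    if dataset_mode is not None:
        try:
            image_interp = DATASET_MODES[dataset_mode]
        except KeyError:
            raise ConfigError(f"unknown dataset mode {dataset_mode!r}; "
                              f"options: {sorted(DATASET_MODES)}") from None
    if image_interp not in _IMAGE_ORDERS:
        raise ConfigError(f"image_interp must be one of {sorted(_IMAGE_ORDERS)}")
    vol = np.asarray(volume, dtype=np.float64)
    lab = np.asarray(labels)
    if vol.shape != lab.shape:
        raise ShapeError(f"image volume {vol.shape} and labels {lab.shape} differ")
    if vol.ndim == 2:
        vol, lab = vol[None], lab[None]
    order = _IMAGE_ORDERS[image_interp]
    out = []
    for z in range(vol.shape[0]):
        zoom = (target_size / vol.shape[1], target_size / vol.shape[2])
        # edge-replicating border keeps constants constant under cubic splines
        img = ndimage.zoom(vol[z], zoom, order=order, grid_mode=True, mode="nearest")
        lz = ndimage.zoom(lab[z], zoom, order=0, grid_mode=True, mode="nearest")
        out.append(SegmentationSample(img[None].astype(np.float32),
                                      lz.astype(np.int64), f"{case_id}_z{z:02d}"))
    return out


# ---------------------------------------------------------------------------
# test-time augmentation


def _tta_transforms(mode: str):
    if mode not in TTA_MODES:
        raise ConfigError(f"unknown TTA mode {mode!r}; options: {sorted(TTA_MODES)}")
    ops = []
    rots = (0,) if mode == "flip" else (0, 1, 2, 3)
    for k in rots:
        for flip in (False, True):
            def fwd(x, k=k, flip=flip):
                y = np.rot90(x, k, axes=(-2, -1))
                return np.ascontiguousarray(np.flip(y, axis=-1) if flip else y)

            def inv(x, k=k, flip=flip):
                y = np.flip(x, axis=-1) if flip else x
                return np.ascontiguousarray(np.rot90(y, -k, axes=(-2, -1)))

            ops.append((fwd, inv))
    return ops


def tta_predict(model: SegmentationNet, images: np.ndarray,
                mode: str = "flip") -> np.ndarray:
    """Average softmax probabilities over the deterministic transform set.

    Returns [N,K,H,W] probabilities summing to 1 per pixel. ``flip`` runs 2
    forward passes, ``flip+rot90`` runs 8.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    ops = _tta_transforms(mode)
    acc = None
    for fwd, inv in ops:
        p = model.predict_proba(fwd(x))
        p = inv(p)
        acc = p if acc is None else acc + p
    acc /= len(ops)
    return acc / acc.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# training loop


def _foreground_dsc(pred: np.ndarray, gt: np.ndarray, num_classes: int) -> float:
    from .metrics import dsc

    vals = [dsc(pred == k, gt == k) for k in range(1, num_classes)]
    return float(np.mean(vals))


def evaluate_dsc(model: SegmentationNet, images: np.ndarray, labels: np.ndarray,
                 batch_size: int = 24) -> float:
    """Mean foreground DSC over a stack of slices (single forward passes)."""
    k = model.config.num_classes
    preds = []
    for i in range(0, len(images), batch_size):
        preds.append(model.predict(images[i:i + batch_size]))
    pred = np.concatenate(preds) if preds else np.empty((0,) + images.shape[2:])
    return _foreground_dsc(pred, labels, k)


def train(model: SegmentationNet, dataset: dict, config: TrainConfig,
          policy: AugmentPolicy | None = None) -> tuple[SegmentationNet, dict]:
    """Train on ``dataset['train']`` with per-epoch validation on
    ``dataset['val']``; keeps the best-validation-DSC weights.

    Fully deterministic given ``config.seed`` on a single device: the seed
    drives batch order and augmentation draws. Raises on non-finite loss.
    Returns the model (best weights restored) and a history dict with
    per-epoch learning rate, training loss and validation DSC.
    """
    config.validate()
    policy = (policy or AugmentPolicy()).validate()
    rng = np.random.default_rng(config.seed)
    xtr = np.asarray(dataset["train"]["images"], dtype=np.float32)
    ytr = np.asarray(dataset["train"]["labels"])
    xval = np.asarray(dataset["val"]["images"], dtype=np.float32)
    yval = np.asarray(dataset["val"]["labels"])
    n = len(xtr)
    if n == 0:
        raise ValueError("empty training set")
    opt = AdamW(model.parameters(), lr=config.base_lr,
                weight_decay=config.weight_decay)
    history = {"epoch": [], "lr": [], "train_loss": [], "val_dsc": []}
    best = (-1.0, None)
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.base_lr, config.min_lr)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            imgs, labs = [], []
            for j in idx:
                s = SegmentationSample(xtr[j], ytr[j])
                if config.augment:
                    s = augment(s, policy, rng)
                imgs.append(s.image)
                labs.append(s.label)
            xb = Tensor(np.stack(imgs), requires_grad=False)
            logits = model(xb)
            loss = hybrid_loss(logits, np.stack(labs), config.alpha, config.beta)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {i // config.batch_size}: "
                    f"{float(loss.data)} (lr={lr:.2e}); aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_dsc = float("nan")
        if len(xval) and (epoch % config.val_every == 0 or epoch == config.epochs - 1):
            val_dsc = evaluate_dsc(model, xval, yval, config.batch_size)
            if val_dsc > best[0]:
                best = (val_dsc, model.state_dict())
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_dsc"].append(val_dsc)
        logger.info("epoch %d: lr=%.2e loss=%.4f val_dsc=%.4f",
                    epoch, lr, history["train_loss"][-1], val_dsc)
    if best[1] is not None:
        model.load_state_dict(best[1])
        history["best_val_dsc"] = best[0]
    model.eval()
    return model, history
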