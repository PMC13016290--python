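"""scikit-learn style front end.

``GatedUNetSegmenter`` wraps model construction and the training loop in a
fit/predict estimator so the segmenter composes with sklearn tooling
(cloning, grid search over architecture switches, pipelines operating on
image stacks). X is a stack of grayscale slices [n, 1, H, W] (or [n, H, W]),
y the integer label maps [n, H, W].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .backbone import BackboneConfig
from .errors import ShapeError
from .model import ModelConfig, SegmentationNet
from .training import TrainConfig, evaluate_dsc, train, tta_predict

__all__ = ["GatedUNetSegmenter"]


class GatedUNetSegmenter(BaseEstimator):
    """Edge-gated attention U-Net segmenter with an sklearn interface.

    The defaults are the desk-scale model used throughout the test suite:
    a (12, 24, 32, 48)-channel encoder and (32, 24, 16, 12) decoder on 64x64
    inputs with 4 classes, trained with the hybrid CE + Dice loss under the
    standard recipe (AdamW, cosine annealing, batch 24, seed 1234).

    Fitted attributes: ``model_`` (the trained network), ``history_``
    (per-epoch loss / validation DSC), ``n_classes_``.
    """

    def __init__(self, num_classes: int = 4,
                 backbone_channels: tuple = (12, 24, 32, 48),
                 decoder_channels: tuple = (32, 24, 16, 12),
                 epochs: int = 12, base_lr: float = 5e-3, batch_size: int = 24,
                 alpha: float = 0.5, beta: float = 0.5, augment: bool = True,
                 attention_stages: tuple = ("D3", "D2"),
                 fusion_strategy: str = "gated_weighted_sum",
                 msag_enabled: bool = True, cam_enabled: bool = True,
                 eaf_enabled: bool = True, eaf_reduction: int = 4,
                 validation_fraction: float = 0.1, seed: int = 1234):
        self.num_classes = num_classes
        self.backbone_channels = backbone_channels
        self.decoder_channels = decoder_channels
        self.epochs = epochs
        self.base_lr = base_lr
        self.batch_size = batch_size
        self.alpha = alpha
        self.beta = beta
        self.augment = augment
        self.attention_stages = attention_stages
        self.fusion_strategy = fusion_strategy
        self.msag_enabled = msag_enabled
        self.cam_enabled = cam_enabled
        self.eaf_enabled = eaf_enabled
        self.eaf_reduction = eaf_reduction
        self.validation_fraction = validation_fraction
        self.seed = seed

    # -- helpers -------------------------------------------------------------
    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None]
        if X.ndim != 4 or X.shape[1] != 1:
            raise ShapeError(f"X must be [n, 1, H, W] or [n, H, W], got {X.shape}")
        return X

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            backbone=BackboneConfig(stage_channels=tuple(self.backbone_channels)),
            num_classes=self.num_classes,
            decoder_channels=tuple(self.decoder_channels),
            attention_stages=tuple(self.attention_stages),
            fusion_strategy=self.fusion_strategy,
            msag_enabled=self.msag_enabled, cam_enabled=self.cam_enabled,
            eaf_enabled=self.eaf_enabled, eaf_reduction=self.eaf_reduction,
            gn_groups=4,
        )

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X = self._check_X(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],) + X.shape[2:]:
            raise ShapeError(f"y {y.shape} does not match X {X.shape}")
        if X_val is None:
            n_val = max(int(round(len(X) * self.validation_fraction)), 1)
            X_val, y_val = X[-n_val:], y[-n_val:]
            X, y = X[:-n_val], y[:-n_val]
        else:
            X_val = self._check_X(X_val)
            y_val = np.asarray(y_val)
        config = TrainConfig(epochs=self.epochs, base_lr=self.base_lr,
                             batch_size=self.batch_size, alpha=self.alpha,
                             beta=self.beta, seed=self.seed,
                             input_size=X.shape[-1], augment=self.augment)
        model = SegmentationNet(self.model_config(), seed=self.seed)
        dataset = {"train": {"images": X, "labels": y},
                   "val": {"images": X_val, "labels": y_val}}
        self.model_, self.history_ = train(model, dataset, config)
        self.n_classes_ = self.num_classes
        return self

    def predict(self, X) -> np.ndarray:
        self._require_fitted()
        return self.model_.predict(self._check_X(X))

    def predict_proba(self, X, tta: str | None = None) -> np.ndarray:
        self._require_fitted()
        X = self._check_X(X)
        if tta is not None:
            return tta_predict(self.model_, X, mode=tta)
        return self.model_.predict_proba(X)

    def score(self, X, y) -> float:
        """Mean foreground Dice similarity coefficient."""
        self._require_fitted()
        return evaluate_dsc(self.model_, self._check_X(X), np.asarray(y),
                            self.batch_size)

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
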