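"""scikit-learn style estimator wrapping the segmentation pipeline.

``UNetSegmenter`` is a classifier over pixels: ``fit`` takes a stack of
grayscale slices and integer label masks, ``predict`` returns label masks,
``predict_proba`` the per-pixel class probabilities.  It composes with
sklearn model selection (get_params/set_params/clone are the standard
BaseEstimator machinery).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .losses import LossWeights
from .nn.unet import NetworkConfig, build_network
from .training import (AugmentConfig, TrainConfig, normalize_slice,
                       predict_batch, train)
from .types import GrayscaleSlice, LabelMask

__all__ = ["UNetSegmenter"]


class UNetSegmenter(BaseEstimator):
    """Batch-normalized U-Net segmenter for 4-class short-axis slices.

    Parameters mirror the network and optimizer configuration: ``depth``
    downsampling stages with ``base_channels`` doubling per stage, trained
    with ADAM on the compound cross-entropy + Dice loss (weights ``alpha``,
    ``beta``).  Slices are min-max normalized per slice before the network.

    Attributes (after fit)
    ----------------------
    network_ : the trained network, batch-norm statistics included
    train_log_ : per-epoch loss / validation Dice records
    classes_ : the label alphabet [0, 1, 2, 3]
    n_parameters_ : trainable parameter count
    """

    def __init__(self, depth: int = 3, base_channels: int = 16,
                 input_size: int = 64, up_mode: str = "transpose",
                 learning_rate: float = 1e-3, batch_size: int = 4,
                 epochs: int = 18, alpha: float = 1.0, beta: float = 0.2,
                 dice_eps: float = 1e-10, dice_mode: str = "joint",
                 augmentation: bool = True, random_state: int = 0):
        self.depth = depth
        self.base_channels = base_channels
        self.input_size = input_size
        self.up_mode = up_mode
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.alpha = alpha
        self.beta = beta
        self.dice_eps = dice_eps
        self.dice_mode = dice_mode
        self.augmentation = augmentation
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _as_pairs(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or y.shape != X.shape:
            raise ValueError("expected X (n, H, W) images and y (n, H, W) masks "
                             f"of equal shape; got {X.shape} and {y.shape}")
        return [(GrayscaleSlice(xi), LabelMask(yi.astype(np.int64)))
                for xi, yi in zip(X, y)]

    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"expected (n, H, W) image stack, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    # -- sklearn surface --------------------------------------------------

    def fit(self, X, y, validation=None):
        """Train on images X (n, H, W) and label masks y (n, H, W).

        ``validation`` is an optional (X_val, y_val) pair used for
        best-epoch checkpoint selection; without it the lowest-training-
        loss epoch is kept.
        """
        pairs = self._as_pairs(X, y)
        val_pairs = self._as_pairs(*validation) if validation is not None else []
        cfg = NetworkConfig(depth=self.depth, base_channels=self.base_channels,
                            input_size=self.input_size, up_mode=self.up_mode,
                            seed=self.random_state)
        tcfg = TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, seed=self.random_state,
            augmentation=AugmentConfig() if self.augmentation
            else AugmentConfig(crop=False, rotation=False,
                               flip_horizontal=False, flip_vertical=False),
            loss=LossWeights(alpha=self.alpha, beta=self.beta,
                             dice_eps=self.dice_eps, dice_mode=self.dice_mode))
        net = build_network(cfg)
        self.network_, self.train_log_ = train(net, pairs, val_pairs, tcfg)
        self.classes_ = np.arange(4)
        self.n_parameters_ = self.network_.n_parameters()
        return self

    def predict(self, X):
        """Segment images; returns (n, H, W) uint8 label masks."""
        self._require_fitted()
        X = self._check_X(X)
        norm = np.stack([normalize_slice(x) for x in X])
        return predict_batch(self.network_, norm)

    def predict_proba(self, X):
        """Per-pixel class probabilities, shape (n, 4, H, W)."""
        from .nn.functional import softmax
        self._require_fitted()
        X = self._check_X(X)
        norm = np.stack([normalize_slice(x) for x in X])[:, None]
        return softmax(self.network_.forward_logits(norm, training=False), axis=1)

    def score(self, X, y):
        """Mean foreground (RV/myo/LV) hard Dice against masks y."""
        from .training import _foreground_dice
        preds = self.predict(X)
        d = _foreground_dice(preds, np.asarray(y))
        return float(np.mean(list(d.values())))

    def _require_fitted(self):
        if not hasattr(self, "network_"):
            raise AttributeError("this UNetSegmenter is not fitted yet; call fit first")
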