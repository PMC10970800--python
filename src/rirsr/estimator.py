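"""Scikit-learn style estimator facade over the network and trainer.

``SuperResolver`` is an image-to-image regressor: ``fit`` consumes
aligned LR/HR patch arrays, ``predict`` super-resolves [0, 255]
grayscale images, and ``score`` reports mean PSNR in dB (higher is
better).  Hyperparameters mirror the architecture and training
configurations one-to-one, so the estimator composes with scikit-learn
model-selection tooling (``get_params`` / ``set_params`` / ``clone``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .degrade import PatchPair
from .metrics import SSIMParams, psnr
from .model import ModelConfig
from .train import TrainConfig, train

__all__ = ["SuperResolver"]


class SuperResolver(BaseEstimator):
    """Residual-in-residual single-image super-resolution estimator.

    Parameters mirror :class:`~rirsr.model.ModelConfig` and
    :class:`~rirsr.train.TrainConfig`; see those classes for semantics.

    Attributes (after ``fit``)
    --------------------------
    model_ : RIRNetwork
        The trained network.
    history_ : TrainHistory
        Per-epoch loss (0-255 intensity units) and learning rate.
    n_parameters_ : int
        Total trainable parameter count.
    """

    def __init__(
        self,
        scale: int = 4,
        n_groups: int = 4,
        n_blocks_per_group: int = 4,
        n_filters: int = 64,
        leaky_slope: float = 0.2,
        use_channel_attention: bool = False,
        use_concat_fusion: bool = True,
        use_skip: bool = True,
        ca_reduction: int = 16,
        upsampler: str = "single",
        lr0: float = 2e-4,
        decay_factor: float = 0.1,
        decay_every: int = 120,
        batch_size: int = 32,
        n_epochs: int = 300,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
        random_state: int = 0,
    ):
        self.scale = scale
        self.n_groups = n_groups
        self.n_blocks_per_group = n_blocks_per_group
        self.n_filters = n_filters
        self.leaky_slope = leaky_slope
        self.use_channel_attention = use_channel_attention
        self.use_concat_fusion = use_concat_fusion
        self.use_skip = use_skip
        self.ca_reduction = ca_reduction
        self.upsampler = upsampler
        self.lr0 = lr0
        self.decay_factor = decay_factor
        self.decay_every = decay_every
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.random_state = random_state

    # -- config assembly ----------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_groups=self.n_groups,
            n_blocks_per_group=self.n_blocks_per_group,
            n_filters=self.n_filters,
            scale=self.scale,
            leaky_slope=self.leaky_slope,
            use_channel_attention=self.use_channel_attention,
            use_concat_fusion=self.use_concat_fusion,
            use_skip=self.use_skip,
            ca_reduction=self.ca_reduction,
            upsampler=self.upsampler,
            seed=self.random_state,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lr0=self.lr0,
            decay_factor=self.decay_factor,
            decay_every=self.decay_every,
            beta1=self.beta1,
            beta2=self.beta2,
            epsilon=self.epsilon,
            batch_size=self.batch_size,
            n_epochs=self.n_epochs,
            seed=self.random_state,
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y) -> "SuperResolver":
        """Fit on aligned patches.

        ``X``: array-like ``(n, p, p)`` of LR patches (0-255 scale) or a
        list of :class:`PatchPair`; ``y``: ``(n, scale*p, scale*p)`` HR
        patches (ignored when ``X`` is already a pair list).
        """
        pairs = self._as_pairs(X, y)
        self.model_, self.history_ = train(
            self._model_config(), pairs, self._train_config()
        )
        self.n_parameters_ = self.model_.n_parameters
        return self

    def _as_pairs(self, X, y) -> list[PatchPair]:
        if len(X) > 0 and isinstance(X[0], PatchPair):
            return list(X)
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 3 or y.ndim != 3 or X.shape[0] != y.shape[0]:
            raise ValueError(
                "expected X of shape (n, p, p) and y of shape (n, s*p, s*p)"
            )
        return [
            PatchPair(lr_patch=X[i], hr_patch=y[i], origin=(0, 0))
            for i in range(X.shape[0])
        ]

    def predict(self, X) -> np.ndarray | list[np.ndarray]:
        """Super-resolve [0, 255] grayscale images.

        Accepts one ``(h, w)`` image, an ``(n, h, w)`` stack, or a list
        of images of possibly different sizes (returned as a list).
        """
        if not hasattr(self, "model_"):
            raise ValueError("SuperResolver is not fitted yet; call fit first")
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return self.model_.predict_image(X)
        outs = [self.model_.predict_image(np.asarray(img)) for img in X]
        if isinstance(X, np.ndarray):
            return np.stack(outs)
        return outs

    def score(self, X, y) -> float:
        """Mean PSNR (dB) of ``predict(X)`` against HR ground truth ``y``."""
        params = SSIMParams()
        preds = self.predict(X)
        return float(np.mean([psnr(p, t, params) for p, t in zip(preds, y)]))
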