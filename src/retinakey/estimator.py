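"""A scikit-learn-style estimator facade over the training pipeline.

The underlying data model (image-pair samples with per-pair annotation
tables) is richer than an (X, y) matrix, so this wrapper adopts the sklearn
*protocol* — ``get_params``/``set_params``/``clone`` compatibility, ``fit``
returning ``self``, fitted attributes with a trailing underscore — while
``fit`` consumes a list of :class:`~retinakey.synth.ImagePairSample`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .evaluation import evaluate_model
from .network import ModelConfig
from .registration import register_pair
from .train import TrainConfig, train

__all__ = ["KeypointRegistrationEstimator"]


class KeypointRegistrationEstimator(BaseEstimator):
    """Trainable keypoint-based registrar with an sklearn-like surface.

    Parameters mirror :class:`~retinakey.train.TrainConfig` and
    :class:`~retinakey.network.ModelConfig`; ``fit`` trains the network,
    ``predict`` registers image pairs, ``score`` returns the success-curve
    AUC on a sample list.
    """

    def __init__(self, context_mode: str = "sapca", match_loss: str = "structured",
                 num_levels: int = 2, base_channels: int = 8,
                 embedding_dim: int = 32, context_kernel_size: int = 5,
                 learning_rate: float = 0.02, iterations: int = 300,
                 margin: float = 1.0, transform_model: str = "similarity",
                 robust: bool = True, random_state: int = 0):
        self.context_mode = context_mode
        self.match_loss = match_loss
        self.num_levels = num_levels
        self.base_channels = base_channels
        self.embedding_dim = embedding_dim
        self.context_kernel_size = context_kernel_size
        self.learning_rate = learning_rate
        self.iterations = iterations
        self.margin = margin
        self.transform_model = transform_model
        self.robust = robust
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, iterations=self.iterations,
            seed=self.random_state, margin=self.margin,
            match_loss=self.match_loss,
            model=ModelConfig(num_levels=self.num_levels,
                              base_channels=self.base_channels,
                              embedding_dim=self.embedding_dim,
                              context_kernel_size=self.context_kernel_size,
                              context_mode=self.context_mode),
        )

    def fit(self, samples, y=None):
        self.model_, self.loss_log_ = train(self._config(), list(samples))
        self.n_iter_ = len(self.loss_log_)
        return self

    def predict(self, samples):
        """Estimated fixed->moving 3x3 matrices (NaN-filled on failure)."""
        self._check_fitted()
        out = []
        for s in samples:
            *_, tform = register_pair(s.fixed_image, s.moving_image, self.model_,
                                      transform_model=self.transform_model,
                                      robust=self.robust)
            out.append(tform.matrix if hasattr(tform, "matrix")
                       else np.full((3, 3), np.nan))
        return np.stack(out)

    def score(self, samples, y=None) -> float:
        self._check_fitted()
        curve, _ = evaluate_model(self.model_, list(samples),
                                  transform_model=self.transform_model,
                                  robust=self.robust)
        return curve.auc

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
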