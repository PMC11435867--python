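"""scikit-learn estimator facade for the patch classifier.

``MJHResNetClassifier`` exposes the network + training protocol through
the familiar ``fit``/``predict``/``predict_proba``/``score`` surface so it
composes with sklearn model selection. ``X`` is a 4-D array of NHWC
patches ``(n, s, s, d)``; ``y`` holds integer class labels.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .model import MJHResNet, ModelConfig
from .patches import PatchDataset
from .train import TrainConfig, train_model

__all__ = ["MJHResNetClassifier"]


class MJHResNetClassifier(ClassifierMixin, BaseEstimator):
    """Hierarchical-residual CNN classifier over spatial-spectral patches.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`;
    fitted state lives in trailing-underscore attributes (``model_``,
    ``classes_``, ``history_``).
    """

    def __init__(
        self,
        channels: int = 64,
        kernel: int = 3,
        blocks_per_branch: int = 6,
        se_reduction: int = 16,
        variant: str = "full",
        epochs_a: int = 70,
        epochs_b: int = 30,
        lr_a: float = 1.0,
        lr_b: float = 0.1,
        batch_size: int = 1024,
        eval_max: int = 2048,
        seed: int = 0,
    ):
        self.channels = channels
        self.kernel = kernel
        self.blocks_per_branch = blocks_per_branch
        self.se_reduction = se_reduction
        self.variant = variant
        self.epochs_a = epochs_a
        self.epochs_b = epochs_b
        self.lr_a = lr_a
        self.lr_b = lr_b
        self.batch_size = batch_size
        self.eval_max = eval_max
        self.seed = seed

    def _validate_X(self, X, fitted: bool) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError(f"X must be 4-D (n, s, s, d) patches, got ndim={X.ndim}")
        if fitted and X.shape[1:] != self._patch_shape_:
            raise ValueError(f"patch shape {X.shape[1:]} does not match fit-time shape {self._patch_shape_}")
        return X

    def fit(self, X, y):
        X = self._validate_X(X, fitted=False)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.classes_ = np.unique(y)
        self._patch_shape_ = X.shape[1:]
        s, d = X.shape[1], X.shape[3]
        cfg = ModelConfig(
            in_bands=d,
            patch_size=s,
            channels=self.channels,
            kernel=self.kernel,
            blocks_per_branch=self.blocks_per_branch,
            se_reduction=self.se_reduction,
            n_classes=self.classes_.size,
            variant=self.variant,
            seed=self.seed,
        )
        # train on everything handed to fit; the split policy lives upstream
        ds = PatchDataset(
            patches=X,
            labels=np.searchsorted(self.classes_, y) + 1,
            coords=np.zeros((X.shape[0], 2), dtype=int),
            patch_size=s,
            split=np.full(X.shape[0], "train", dtype="<U5"),
        )
        tcfg = TrainConfig(
            epochs_a=self.epochs_a,
            epochs_b=self.epochs_b,
            lr_a=self.lr_a,
            lr_b=self.lr_b,
            batch_size=self.batch_size,
            eval_max=self.eval_max,
            seed=self.seed,
        )
        self.model_ = MJHResNet(cfg)
        self.model_, self.history_ = train_model(self.model_, ds, tcfg)
        return self

    def decision_function(self, X):
        X = self._validate_X(X, fitted=True)
        return self.model_.predict_logits(X)

    def predict_proba(self, X):
        logits = self.decision_function(X)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]
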