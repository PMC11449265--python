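"""Scikit-learn style estimator wrapping the two-stage volume classifier.

``VolumeClassifier`` follows the sklearn estimator contract — constructor
parameters mirror :class:`glomil.io.RunConfig`, ``get_params`` /
``set_params`` work, fitted state lives in trailing-underscore
attributes — so the model composes with sklearn model selection.  X is a
list of (H, W, D) arrays (stacks may have different slice counts), y an
(n, 2) binary array of (benign, malignant) labels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import model as _model
from .io import RunConfig

__all__ = ["VolumeClassifier"]

_CONFIG_FIELDS = [f.name for f in dataclasses.fields(RunConfig)]


class VolumeClassifier(BaseEstimator, ClassifierMixin):
    """Two-stage global/local multiple-instance classifier for 3D stacks.

    Parameters are documented on :class:`glomil.io.RunConfig`; the extra
    ``val_fraction`` controls the internal train/validation split used
    for early stopping when ``fit`` is not given explicit splits.

    Attributes (after fit)
    ----------------------
    net_ : the trained network
    history_ : per-epoch log (loss, validation AUCs)
    best_val_auc_ : best malignant-class validation AUC
    classes_ : (2,) class indicator columns (benign, malignant)
    """

    def __init__(self, t=142.61, omega=10 ** -2.5, backbone_width=16,
                 backbone_downsample=16, saliency_nonlinearity="relu_tanh",
                 K=8, zeta=10, patch_size=256, patch_width=16, feature_dim=512,
                 attention_dim=128, learning_rate=10 ** -5.0, beta=10 ** -5.54,
                 epochs=40, early_stop_patience=15, batch_size=4, seed=0,
                 tta_count=10, max_shift=100, max_rescale=0.1,
                 val_fraction=0.2):
        self.t = t
        self.omega = omega
        self.backbone_width = backbone_width
        self.backbone_downsample = backbone_downsample
        self.saliency_nonlinearity = saliency_nonlinearity
        self.K = K
        self.zeta = zeta
        self.patch_size = patch_size
        self.patch_width = patch_width
        self.feature_dim = feature_dim
        self.attention_dim = attention_dim
        self.learning_rate = learning_rate
        self.beta = beta
        self.epochs = epochs
        self.early_stop_patience = early_stop_patience
        self.batch_size = batch_size
        self.seed = seed
        self.tta_count = tta_count
        self.max_shift = max_shift
        self.max_rescale = max_rescale
        self.val_fraction = val_fraction

    # -- config plumbing --------------------------------------------------------
    def _config(self) -> RunConfig:
        return RunConfig(**{k: getattr(self, k) for k in _CONFIG_FIELDS}).validate()

    @classmethod
    def from_config(cls, config: RunConfig, **extra) -> "VolumeClassifier":
        return cls(**dataclasses.asdict(config), **extra)

    # -- sklearn surface ---------------------------------------------------------
    def fit(self, X, y, splits=None, verbose: bool = False):
        """Train on volumes X (list of (H, W, D) arrays) and labels y (n, 2).

        ``splits`` may assign "train"/"val" per sample; otherwise the last
        ``val_fraction`` of the samples (by position) form the validation
        split used for early stopping and model selection.
        """
        X = [np.asarray(v) for v in X]
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError(f"y must be (n_samples, 2), got {y.shape}")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if splits is None:
            n_val = max(1, int(round(self.val_fraction * len(X))))
            splits = ["train"] * (len(X) - n_val) + ["val"] * n_val
        result = _model.train(X, y, list(splits), self._config(), verbose=verbose)
        self.net_ = result.net
        self.history_ = result.log
        self.best_val_auc_ = result.best_val_auc
        self.best_epoch_ = result.best_epoch
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X, tta: bool = False, seed: int = 0) -> np.ndarray:
        """Final (benign, malignant) probabilities, optionally TTA-averaged."""
        self._check_fitted()
        rng = np.random.default_rng(seed)
        out = []
        for v in X:
            v = np.asarray(v)
            if tta:
                out.append(_model.tta_predict(v, self.net_, self.tta_count, rng))
            else:
                out.append(self.net_.predict(v).p_final)
        return np.asarray(out)

    def predict(self, X) -> np.ndarray:
        """Binary (n, 2) label predictions at the 0.5 probability point."""
        return (self.predict_proba(X) >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)

    # -- localization surface ------------------------------------------------------
    def saliency(self, volume) -> np.ndarray:
        """(h, w, D, 2) saliency stack for one volume."""
        self._check_fitted()
        return self.net_.predict(np.asarray(volume)).saliency

    def locate(self, volume):
        """Full model output: probabilities, saliency, patch locations, attention."""
        self._check_fitted()
        return self.net_.predict(np.asarray(volume))

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit first")
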