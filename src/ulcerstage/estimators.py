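"""Scikit-learn style estimators wrapping the staging network.

:class:`WoundStageTransformer` is a single classifier (one backbone, one
training run); :class:`KFoldEnsembleClassifier` trains one per stratified
fold and predicts with the two-tier (checkpoint-epoch, then fold)
probability average.  Both follow the sklearn contract — ``fit`` /
``predict`` / ``predict_proba``, ``get_params`` round-trip, fitted
attributes with trailing underscores — so they compose with pipelines
and model selection.

``X`` is a float array of preprocessed images ``(n_samples, 3, H, W)``
(see :func:`ulcerstage.data_io.preprocess_batch`); ``y`` may be taxonomy
codes or integer indices.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .augment import MixupConfig
from .losses import FocalLossConfig, ScheduleConfig
from .model import BackboneSpec, StagingNetwork
from .training import TrainConfig, fit_network, stratified_kfold


class WoundStageTransformer(BaseEstimator, ClassifierMixin):
    """Hierarchical-attention transformer classifier for wound staging.

    Defaults describe the desk-scale configuration (a miniature encoder
    trained from random init); pass ``depth=12, dim=768, heads=12,
    image_size=224, patch_size=16, tap_blocks=(6, 9, 12), eta_max=2e-5``
    for the full-scale geometry.
    """

    def __init__(self, image_size: int = 32, patch_size: int = 8, depth: int = 2,
                 dim: int = 32, heads: int = 4, tap_blocks: tuple[int, ...] | None = None,
                 use_enhanced_attention: bool = True, use_hierarchical_fusion: bool = True,
                 head_dropout: float = 0.1, stochastic_depth: float = 0.0,
                 epochs: int = 12, eta_max: float = 6e-3, eta_min: float = 0.0,
                 t_warmup: int = 1, micro_batch: int = 8, accumulation: int = 2,
                 weight_decay: float = 0.04, patience: int = 7,
                 checkpoint_epochs: tuple[int, ...] = (),
                 mixup_alpha: float = 0.2, use_mixup: bool = False,
                 beta: float = 0.9999, gamma: float = 3.0,
                 mixed_precision: bool = False, random_state: int = 0):
        self.image_size = image_size
        self.patch_size = patch_size
        self.depth = depth
        self.dim = dim
        self.heads = heads
        self.tap_blocks = tap_blocks
        self.use_enhanced_attention = use_enhanced_attention
        self.use_hierarchical_fusion = use_hierarchical_fusion
        self.head_dropout = head_dropout
        self.stochastic_depth = stochastic_depth
        self.epochs = epochs
        self.eta_max = eta_max
        self.eta_min = eta_min
        self.t_warmup = t_warmup
        self.micro_batch = micro_batch
        self.accumulation = accumulation
        self.weight_decay = weight_decay
        self.patience = patience
        self.checkpoint_epochs = checkpoint_epochs
        self.mixup_alpha = mixup_alpha
        self.use_mixup = use_mixup
        self.beta = beta
        self.gamma = gamma
        self.mixed_precision = mixed_precision
        self.random_state = random_state

    # -- plumbing ---------------------------------------------------------
    def _backbone_spec(self) -> BackboneSpec:
        taps = self.tap_blocks if self.tap_blocks is not None else tuple(
            range(1, self.depth + 1))
        return BackboneSpec(depth=self.depth, dim=self.dim, heads=self.heads,
                            patch_size=self.patch_size, img_size=self.image_size,
                            tap_blocks=taps)

    def _train_config(self) -> TrainConfig:
        sched = ScheduleConfig(eta_max=self.eta_max, eta_min=self.eta_min,
                               t_warmup=self.t_warmup, t_total=max(self.epochs, self.t_warmup + 1))
        return TrainConfig(schedule=sched, weight_decay=self.weight_decay,
                           micro_batch=self.micro_batch, accumulation=self.accumulation,
                           patience=self.patience,
                           checkpoint_epochs=tuple(self.checkpoint_epochs),
                           max_epochs=self.epochs,
                           mixed_precision=self.mixed_precision,
                           mixup=MixupConfig(self.mixup_alpha) if self.use_mixup else None,
                           seed=self.random_state)

    def _validate_X(self, X, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[1] != 3:
            raise ValueError(f"X must be (n_samples, 3, H, W), got {X.shape}")
        if X.shape[2] != self.image_size or X.shape[3] != self.image_size:
            raise ValueError(f"images must be {self.image_size}px, got {X.shape[2:]}")
        return X

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train; validation data (for early stopping / history) defaults to
        the training set when not supplied."""
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError(f"{len(X)} samples but {len(y)} labels")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        if X_val is None:
            Xv, yv = X, y_idx
        else:
            Xv = self._validate_X(X_val)
            class_to_idx = {c: i for i, c in enumerate(self.classes_)}
            yv = np.asarray([class_to_idx[c] for c in np.asarray(y_val)])
        counts = np.bincount(y_idx, minlength=len(self.classes_))
        loss_cfg = FocalLossConfig(beta=self.beta, gamma=self.gamma,
                                   class_counts=tuple(int(max(c, 1)) for c in counts))
        net = StagingNetwork(
            self._backbone_spec(), n_classes=len(self.classes_),
            use_enhanced_attention=self.use_enhanced_attention,
            use_hierarchical_fusion=self.use_hierarchical_fusion,
            head_dropout=self.head_dropout, stochastic_depth=self.stochastic_depth,
            seed=self.random_state,
            dtype=np.float32 if self.mixed_precision else np.float64)
        history, snapshots, best_epoch = fit_network(
            net, X, y_idx, Xv, yv, self._train_config(), loss_cfg)
        net.load_state_dict(snapshots["best"])
        self.network_ = net
        self.history_ = history
        self.snapshots_ = snapshots
        self.best_epoch_ = best_epoch
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        return self.network_.predict_proba(self._validate_X(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def predict_proba_at(self, X, snapshot: str) -> np.ndarray:
        """Probabilities from a stored checkpoint ('epochN' or 'best')."""
        check_is_fitted(self, "network_")
        if snapshot not in self.snapshots_:
            raise KeyError(f"no snapshot {snapshot!r}; have {sorted(self.snapshots_)}")
        current = self.network_.state_dict()
        try:
            self.network_.load_state_dict(self.snapshots_[snapshot])
            return self.network_.predict_proba(self._validate_X(X))
        finally:
            self.network_.load_state_dict(current)


class KFoldEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Two-tier ensemble: checkpoint epochs within folds, then across folds.

    ``fit`` trains ``n_folds`` base classifiers on stratified folds of the
    training data; ``predict_proba`` averages each fold's checkpoint-epoch
    probability matrices (temporal tier, falling back to the best epoch if
    training stopped before every checkpoint) and then averages folds
    (spatial tier).
    """

    def __init__(self, base: WoundStageTransformer | None = None, n_folds: int = 5,
                 checkpoint_epochs: tuple[int, ...] = (15, 20, 25, 30),
                 random_state: int = 0):
        self.base = base
        self.n_folds = n_folds
        self.checkpoint_epochs = checkpoint_epochs
        self.random_state = random_state

    def fit(self, X, y):
        base = self.base if self.base is not None else WoundStageTransformer()
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        assignment = stratified_kfold(y, self.n_folds, self.random_state)
        self.fold_estimators_ = []
        self.fold_histories_ = []
        for f, (train_idx, val_idx) in enumerate(assignment.folds):
            est = clone(base)
            est.set_params(checkpoint_epochs=tuple(self.checkpoint_epochs),
                           random_state=self.random_state + f)
            est.fit(X[train_idx], y[train_idx], X_val=X[val_idx], y_val=y[val_idx])
            self.fold_estimators_.append(est)
            self.fold_histories_.append(est.history_)
        self.assignment_ = assignment
        best_f1 = [max(r["val_macro_f1"] for r in h) for h in self.fold_histories_]
        self.cv_summary_ = {
            "val_macro_f1_mean": float(np.mean(best_f1)),
            "val_macro_f1_sd": float(np.std(best_f1, ddof=1)) if len(best_f1) > 1 else 0.0,
        }
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "fold_estimators_")
        fold_means = []
        for est in self.fold_estimators_:
            names = [f"epoch{e}" for e in self.checkpoint_epochs if f"epoch{e}" in est.snapshots_]
            if not names:  # fold stopped before any checkpoint epoch
                names = ["best"]
            members = [est.predict_proba_at(X, name) for name in names]
            fold_means.append(np.mean(members, axis=0))
        return np.mean(fold_means, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
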