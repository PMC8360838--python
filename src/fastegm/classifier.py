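"""Sklearn-style estimators: the 1-D residual CNN and classic baselines.

:class:`ResNet1DClassifier` wraps the numpy residual network in the sklearn
estimator contract (``fit`` / ``predict_proba`` / ``get_params``), so it
composes with pipelines and model selection.  ``fit_baseline`` builds the
classic comparators — logistic regression, polynomial-kernel SVM (degree 3
or 10) and KNN (k = 10 or 50) — on the same preprocessed input vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .nn.resnet import ResNet1d
from .nn.train import TrainConfig, train_network
from .prep import AugmentConfig, minmax_scale

__all__ = ["ResNet1DClassifier", "BaselineSpec", "fit_baseline",
           "baseline_scores", "grid_search_hyperparams"]


class ResNet1DClassifier(ClassifierMixin, BaseEstimator):
    """1-D residual CNN classifier of FaST vs non-FaST unipolar traces.

    Expects unscaled 200-Hz traces of ``input_length`` samples; min-max
    scaling (and, during training, the stochastic augmentations) is applied
    internally.  ``fit`` holds out a validation split — by patient when
    ``groups`` are given — and restores the epoch checkpoint with the best
    validation AUC.

    Attributes
    ----------
    model_ : ResNet1d
        The trained network.
    history_ : list of dict
        Per-epoch training/validation loss and validation AUC.
    classes_ : ndarray
        Always ``[0, 1]``.
    """

    def __init__(self, input_length: int = 1000,
                 stage_channels: tuple[int, ...] = (64, 128, 256, 512),
                 stage_blocks: tuple[int, ...] = (2, 2, 2, 2),
                 dropout_rate: float = 0.2, batch_size: int = 64,
                 learning_rate: float = 1e-3, scheduler: str = "plateau",
                 epochs: int = 30, augment_probability: float = 0.5,
                 validation_fraction: float = 0.2, random_state: int = 0):
        self.input_length = input_length
        self.stage_channels = stage_channels
        self.stage_blocks = stage_blocks
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.scheduler = scheduler
        self.epochs = epochs
        self.augment_probability = augment_probability
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _split(self, X, y, groups, rng):
        n = len(X)
        if groups is not None:
            uniq = np.unique(groups)
            rng.shuffle(uniq)
            n_val = max(int(round(self.validation_fraction * len(uniq))), 1)
            val_groups = set(uniq[:n_val])
            val_mask = np.array([g in val_groups for g in groups])
        else:
            idx = rng.permutation(n)
            n_val = max(int(round(self.validation_fraction * n)), 1)
            val_mask = np.zeros(n, dtype=bool)
            val_mask[idx[:n_val]] = True
        if val_mask.all() or not val_mask.any():
            raise ValueError("validation split is degenerate")
        return ~val_mask, val_mask

    def fit(self, X, y, groups=None, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_length:
            raise ValueError(f"X must be (n, {self.input_length})")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            tr, va = self._split(X, y, groups, rng)
            X_tr, y_tr, X_va, y_va = X[tr], y[tr], X[va], y[va]
        else:
            X_tr, y_tr = X, y
            X_va, y_va = np.asarray(X_val, dtype=float), np.asarray(y_val, dtype=float)
        model = ResNet1d(input_length=self.input_length,
                         stage_channels=tuple(self.stage_channels),
                         stage_blocks=tuple(self.stage_blocks),
                         dropout_rate=self.dropout_rate,
                         seed=self.random_state)
        tcfg = TrainConfig(batch_size=self.batch_size,
                           learning_rate=self.learning_rate,
                           scheduler=self.scheduler, epochs=self.epochs,
                           seed=self.random_state)
        acfg = (AugmentConfig(probability=self.augment_probability,
                              seed=self.random_state)
                if self.augment_probability > 0 else None)
        self.model_, self.history_ = train_network(
            model, X_tr, y_tr, X_va, y_va, tcfg, acfg)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        Xs = np.stack([minmax_scale(row) for row in X])
        return self.model_.predict_proba(Xs)

    def predict_proba(self, X):
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0.5).astype(int)


@dataclass
class BaselineSpec:
    """A classic-ML comparator: logistic regression, SVM or KNN."""

    kind: str
    svm_degree: int | None = None
    knn_k: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "svm":
            if self.svm_degree not in (3, 10):
                raise ValueError("svm requires svm_degree in {3, 10}")
        elif self.kind == "knn":
            if self.knn_k not in (10, 50):
                raise ValueError("knn requires knn_k in {10, 50}")
        elif self.kind == "logistic_regression":
            if self.svm_degree is not None or self.knn_k is not None:
                raise ValueError("logistic_regression takes no hyper-parameter")
        else:
            raise ValueError(f"unknown baseline kind {self.kind!r}")


def fit_baseline(spec: BaselineSpec, X, y, random_state: int = 0):
    """Fit a baseline on the same preprocessed vectors the network consumes."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if spec.kind == "logistic_regression":
        est = LogisticRegression(max_iter=2000, random_state=random_state)
    elif spec.kind == "svm":
        est = SVC(kernel="poly", degree=spec.svm_degree, random_state=random_state)
    else:
        if spec.knn_k > len(X):
            raise ValueError(f"knn_k={spec.knn_k} exceeds training size {len(X)}")
        est = KNeighborsClassifier(n_neighbors=spec.knn_k)
    return est.fit(X, y)


def baseline_scores(est, X) -> np.ndarray:
    """Continuous scores for ROC analysis from any fitted baseline."""
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


def grid_search_hyperparams(
    X, y, groups,
    batch_sizes=(32, 64, 128),
    learning_rates=(1e-2, 1e-3, 1e-4),
    schedulers=("plateau", "cosine"),
    n_folds: int = 3,
    base_params: dict | None = None,
    random_state: int = 0,
):
    """Grid search over batch size, learning rate and scheduler with
    patient-level k-fold cross-validation; returns (best_params, table)."""
    from .evaluate import patient_folds  # local import to avoid a cycle

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    results = []
    for bs, lr, sched in itertools.product(batch_sizes, learning_rates, schedulers):
        aucs = []
        for tr, te in patient_folds(groups, n_folds, seed=random_state):
            params = dict(base_params or {})
            params.update(batch_size=bs, learning_rate=lr, scheduler=sched,
                          random_state=random_state)
            clf = ResNet1DClassifier(**params).fit(X[tr], y[tr], groups=groups[tr])
            aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
        results.append({"batch_size": bs, "learning_rate": lr,
                        "scheduler": sched, "mean_auc": float(np.mean(aucs))})
    best = max(results, key=lambda r: r["mean_auc"])
    return {k: best[k] for k in ("batch_size", "learning_rate", "scheduler")}, results
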