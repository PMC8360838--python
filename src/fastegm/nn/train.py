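"""Training loop for the 1-D residual classifier.

Trains with Adam on binary cross-entropy, applying the stochastic
augmentation pipeline to each training trace anew every epoch, and keeps
the checkpoint with the best validation AUC.  All randomness (shuffling,
augmentation draws, dropout) flows from one seeded generator, so repeated
runs reproduce the history to floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from ..prep import AugmentConfig, augment_pipeline, minmax_scale
from .optim import Adam, bce_with_logits
from .resnet import ResNet1d

__all__ = ["TrainConfig", "train_network", "predict_proba"]


@dataclass
class TrainConfig:
    """Optimization hyper-parameters.

    The defaults (batch 64, Adam at 1e-3 with a reduce-on-plateau schedule,
    30 epochs) are the package's defaults; a grid-search utility over batch
    size, learning rate and scheduler lives in the classifier module.
    """

    batch_size: int = 64
    learning_rate: float = 1e-3
    scheduler: str = "plateau"          # "plateau" | "cosine" | "none"
    plateau_factor: float = 0.5
    plateau_patience: int = 3
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.scheduler not in ("plateau", "cosine", "none"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")


def _prepare_epoch(X: np.ndarray, augment_config: AugmentConfig | None,
                   rng: np.random.Generator) -> np.ndarray:
    """Augment-and-scale every training trace for one epoch."""
    if augment_config is None or augment_config.probability == 0.0:
        return np.stack([minmax_scale(row) for row in X])
    return np.stack([
        augment_pipeline(row, augment_config,
                         seed=int(rng.integers(0, 2**31))).values
        for row in X
    ])


def train_network(model: ResNet1d, X_train: np.ndarray, y_train: np.ndarray,
                  X_val: np.ndarray, y_val: np.ndarray,
                  config: TrainConfig | None = None,
                  augment_config: AugmentConfig | None = None,
                  ) -> tuple[ResNet1d, list[dict]]:
    """Train ``model`` and return it loaded with the best-validation-AUC
    checkpoint, along with the per-epoch history.

    ``X_train``/``X_val`` are unscaled 200-Hz traces; validation traces are
    min-max scaled only, training traces are re-augmented each epoch.
    """
    config = config or TrainConfig()
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    model.dropout.rng = np.random.default_rng(int(rng.integers(0, 2**31)))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    Xv = np.stack([minmax_scale(row) for row in X_val])
    history: list[dict] = []
    best_auc, best_state = -np.inf, None
    plateau_best, plateau_wait = np.inf, 0
    n = len(X_train)
    for epoch in range(config.epochs):
        if config.scheduler == "cosine":
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / max(config.epochs - 1, 1)))
        Xe = _prepare_epoch(X_train, augment_config, rng)
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need at least two samples
            model.zero_grad()
            logit = model.forward(Xe[idx], train=True)
            loss, dlogit = bce_with_logits(logit, y_train[idx])
            model.backward(dlogit)
            opt.step()
            losses.append(loss)
        val_scores = model.predict_proba(Xv)
        val_loss, _ = bce_with_logits(
            np.log(val_scores / (1.0 - val_scores + 1e-12) + 1e-12), y_val)
        val_auc = (roc_auc_score(y_val, val_scores)
                   if len(np.unique(y_val)) > 1 else np.nan)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": float(val_loss), "val_auc": float(val_auc),
                        "lr": float(opt.lr)})
        if np.isfinite(val_auc) and val_auc > best_auc:
            best_auc, best_state = val_auc, model.state()
        if config.scheduler == "plateau":
            if val_loss < plateau_best - 1e-6:
                plateau_best, plateau_wait = val_loss, 0
            else:
                plateau_wait += 1
                if plateau_wait > config.plateau_patience:
                    opt.lr *= config.plateau_factor
                    plateau_wait = 0
    if best_state is not None:
        model.load_state(best_state)
    return model, history


def predict_proba(model: ResNet1d, X: np.ndarray) -> np.ndarray:
    """Scale and score unscaled 200-Hz traces."""
    Xs = np.stack([minmax_scale(row) for row in np.asarray(X, dtype=float)])
    return model.predict_proba(Xs)
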