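"""Training configuration, checkpoint selection, and prediction helpers.

The heavy lifting lives in the estimators
(:class:`~fundusprog.estimators.FundusPairClassifier`,
:class:`~fundusprog.estimators.FundusForecaster`); this module provides
the configuration records, the learning-rate schedule of the GAN, the
checkpoint bookkeeping (lowest validation loss within a run, highest
validation AUC across a hyperparameter sweep), and single-/multi-step
future-image prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .estimators import FundusForecaster, FundusPairClassifier
from .models import generator_forward


@dataclass(frozen=True)
class ClassifierTrainConfig:
    epochs: int = 20
    eval_every_iters: int = 50
    lr: float = 1e-3
    betas: tuple = (0.9, 0.999)
    batch_size: int = 32
    width_scale: float = 0.25
    age_fusion: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.eval_every_iters < 1:
            raise ValueError("eval_every_iters must be >= 1")


@dataclass(frozen=True)
class GanTrainConfig:
    epochs: int = 200
    batch_size: int = 1  # fixed: pairs must not share normalization statistics
    lr: float = 2e-4
    betas: tuple = (0.5, 0.999)
    decay_start_epoch: int = 100
    lambda_r: float = 100.0
    input_size: int = 64
    depth: int = 6
    base_channels: int = 16
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.batch_size != 1:
            raise ValueError("GAN batch size is fixed at 1")
        if not 1 <= self.decay_start_epoch <= self.epochs:
            raise ValueError("decay_start_epoch must be in 1..epochs")


@dataclass
class Checkpoint:
    """A saved model state with the metrics recorded at save time."""

    weights: list
    hyperparams: dict
    val_loss: float
    val_auc: float
    iteration: int


def gan_lr_schedule(epoch: int, epochs: int, decay_start_epoch: int,
                    base_lr: float) -> float:
    """Constant for ``decay_start_epoch`` epochs, then linear decay to 0.

    Epochs are 1-based; the returned rate reaches exactly 0 at
    ``epochs`` (the rate used *during* the final epoch is the last
    nonzero step of the ramp).
    """
    if epoch <= decay_start_epoch:
        return base_lr
    span = epochs - decay_start_epoch
    return base_lr * max(0.0, 1.0 - (epoch - decay_start_epoch) / span)


def train_classifier(X, y, X_val, y_val, cfg: ClassifierTrainConfig,
                     age=None, age_val=None):
    """Train a pair classifier; return ``(estimator, Checkpoint)``.

    The checkpoint holds the weights with the lowest validation
    weighted cross-entropy among all periodic evaluations.
    """
    if len(np.asarray(y)) == 0:
        raise ValueError("empty training set")
    est = FundusPairClassifier(
        width_scale=cfg.width_scale, age_fusion=cfg.age_fusion, lr=cfg.lr,
        batch_size=cfg.batch_size, epochs=cfg.epochs,
        eval_every_iters=cfg.eval_every_iters, random_state=cfg.seed,
    ).fit(X, y, X_val=X_val, y_val=y_val, age=age, age_val=age_val)
    from . import nn

    ckpt = Checkpoint(weights=nn.get_weights(est.net_), hyperparams=asdict(cfg),
                      val_loss=est.val_loss_, val_auc=est.val_auc_,
                      iteration=est.best_iteration_)
    return est, ckpt


def sweep_select(checkpoints: Sequence[Checkpoint]) -> Checkpoint:
    """Pick the sweep winner: highest validation AUC, ties broken by
    lower validation loss, then earlier iteration."""
    cks = list(checkpoints)
    if not cks:
        raise ValueError("empty checkpoint list")
    return min(cks, key=lambda c: (-c.val_auc, c.val_loss, c.iteration))


def train_gan(X_first, X_second, Xv_first, Xv_second, cfg: GanTrainConfig):
    """Train the forecaster; return ``(estimator, best_ckpt, final_ckpt)``.

    ``best`` is the generator state with the lowest validation L1;
    ``final`` the state after the last epoch (the estimator keeps the
    final weights loaded; call ``estimator.use_best()`` to switch).
    """
    est = FundusForecaster(
        input_size=cfg.input_size, depth=cfg.depth,
        base_channels=cfg.base_channels, dropout_rate=cfg.dropout_rate,
        epochs=cfg.epochs, lr=cfg.lr, beta1=cfg.betas[0], beta2=cfg.betas[1],
        decay_start_epoch=cfg.decay_start_epoch, lambda_r=cfg.lambda_r,
        random_state=cfg.seed,
    ).fit(X_first, X_second, X_val=Xv_first, Y_val=Xv_second)
    hp = asdict(cfg)
    best = Checkpoint(weights=est.best_weights_, hyperparams=hp,
                      val_loss=est.best_val_l1_, val_auc=float("nan"),
                      iteration=est.best_epoch_)
    final = Checkpoint(weights=est.final_weights_, hyperparams=hp,
                       val_loss=est.history_[-1]["val_l1"], val_auc=float("nan"),
                       iteration=cfg.epochs)
    return est, best, final


def predict_future(generator, image, stochastic: bool = False) -> np.ndarray:
    """One-step forecast of the next image at the trained gap.

    ``generator`` is a raw U-Net (images in [-1, 1], channels first) or
    a fitted :class:`FundusForecaster` (channels-last [0, 1]).
    """
    if isinstance(generator, FundusForecaster):
        x = np.asarray(image)
        return generator.transform(x[None], stochastic=stochastic)[0]
    return generator_forward(generator, image, stochastic=stochastic)


def predict_multistep(generator, image, k: int, stochastic: bool = False) -> list:
    """Iterate the one-gap forecast ``k`` times; element i+1 = G(element i)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    out = []
    x = image
    for _ in range(k):
        x = predict_future(generator, x, stochastic=stochastic)
        out.append(x)
    return out
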