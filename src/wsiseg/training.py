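"""Training loop: batch 8, at most 50 epochs, early stopping patience 5.

The loss is per-pixel categorical cross-entropy over the three tissue
classes with background pixels excluded (they carry no annotation, so
they contribute exactly zero gradient); a soft-Dice loss is available
as an option. Optimisation uses Adam. Validation loss is monitored
each epoch; training stops once it has failed to improve (by at least
``min_delta``) for ``early_stop_patience`` consecutive epochs, and the
best epoch's weights are restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .dataset import DatasetSplit, load_batch
from .metrics import evaluate_dataset

logger = logging.getLogger("wsiseg.training")

__all__ = ["TrainConfig", "TrainHistory", "EarlyStopping", "train",
           "evaluate_loss", "predict_batches"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    max_epochs: int = 50
    early_stop_patience: int = 5
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    loss: str = "cross_entropy"        # or "dice"
    min_delta: float = 1e-4            # improvement tolerance for float noise
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.loss not in ("cross_entropy", "dice"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer_name not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": range(1, len(self.train_loss) + 1),
                             "train_loss": self.train_loss,
                             "val_loss": self.val_loss,
                             "val_dice": self.val_dice})

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


class EarlyStopping:
    """Stops when the monitored loss has not improved for ``patience``
    consecutive epochs; an improvement must beat the best value by at
    least ``min_delta``."""

    def __init__(self, patience: int = 5, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = 0
        self.epochs_without_improvement = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.best_epoch = epoch
            self.epochs_without_improvement = 0
            return False
        self.epochs_without_improvement += 1
        return self.epochs_without_improvement >= self.patience


def _loss_fn(cfg: TrainConfig):
    return (nn.softmax_cross_entropy if cfg.loss == "cross_entropy"
            else nn.soft_dice_loss)


def _to_nchw(x: np.ndarray) -> nn.Tensor:
    return nn.Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))


def evaluate_loss(net, part, cfg: TrainConfig, root=None) -> float:
    """Mean loss over a split part in evaluation mode."""
    was_training = net.training
    net.eval()
    loss_fn = _loss_fn(cfg)
    total, n = 0.0, 0
    try:
        for x, y, ignore in load_batch(part, cfg.batch_size, root=root):
            loss = loss_fn(net(_to_nchw(x)).detach(), y, ignore)
            total += float(loss.data) * len(x)
            n += len(x)
    finally:
        net.train(was_training)
    return total / max(1, n)


def predict_batches(net, part, batch_size: int = 8, root=None):
    """Argmax predictions for a split part: lists of (pred, gt, ignore)."""
    preds, gts, igns = [], [], []
    for x, y, ignore in load_batch(part, batch_size, root=root):
        p = net.predict_proba(x).argmax(axis=-1)
        preds.extend(p)
        gts.extend(y)
        igns.extend(ignore)
    return preds, gts, igns


def _mean_dice(net, part, batch_size, root=None) -> float:
    preds, gts, igns = predict_batches(net, part, batch_size, root=root)
    report = evaluate_dataset(preds, gts, igns)
    return report.average["dice"]


def train(net, split: DatasetSplit | tuple, cfg: TrainConfig = TrainConfig(),
          root=None, compute_val_dice: bool = True) -> TrainHistory:
    """Train ``net`` on a split's train part, early-stopping on val loss.

    ``split`` is a :class:`DatasetSplit` or a ``(train, val)`` pair of
    patch lists / manifest frames. Restores the best epoch's weights
    before returning.
    """
    if isinstance(split, DatasetSplit):
        train_part, val_part = split.train, split.val
    else:
        train_part, val_part = split
    if len(train_part) == 0:
        raise ValueError("training part is empty")
    if len(val_part) == 0:
        raise ValueError("validation part is empty (needed for early "
                         "stopping); use fractions with a val share")

    loss_fn = _loss_fn(cfg)
    params = [p for p in net.parameters() if p.trainable]
    if cfg.optimizer_name == "adam":
        opt = nn.Adam(params, lr=cfg.learning_rate)
    else:
        opt = nn.SGD(params, lr=cfg.learning_rate)
    stopper = EarlyStopping(cfg.early_stop_patience, cfg.min_delta)
    history = TrainHistory()
    best_state = net.state_dict()

    net.train()
    for epoch in range(1, cfg.max_epochs + 1):
        epoch_loss, n_seen = 0.0, 0
        shuffle_seed = cfg.seed + epoch  # deterministic per-epoch order
        for x, y, ignore in load_batch(train_part, cfg.batch_size,
                                       shuffle_seed=shuffle_seed, root=root):
            net.zero_grad()
            loss = loss_fn(net(_to_nchw(x)), y, ignore)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite training loss ({lv}) at epoch {epoch}; "
                    "try a lower learning rate")
            loss.backward()
            opt.step()
            epoch_loss += lv * len(x)
            n_seen += len(x)
        history.train_loss.append(epoch_loss / n_seen)
        vl = evaluate_loss(net, val_part, cfg, root=root)
        history.val_loss.append(vl)
        vd = (_mean_dice(net, val_part, cfg.batch_size, root=root)
              if compute_val_dice else float("nan"))
        history.val_dice.append(vd)
        logger.info("epoch %d: train_loss=%.4f val_loss=%.4f val_dice=%.4f",
                    epoch, history.train_loss[-1], vl, vd)
        improved_to_best = vl < stopper.best - stopper.min_delta
        stop = stopper.update(vl, epoch)
        if improved_to_best:
            best_state = net.state_dict()
        history.stopped_epoch = epoch
        if stop:
            logger.info("early stopping at epoch %d (best epoch %d)",
                        epoch, stopper.best_epoch)
            break

    history.best_epoch = stopper.best_epoch or 1
    net.load_state_dict(best_state)
    return history
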