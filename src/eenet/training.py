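"""Training and evaluation loop for the edge-enhanced segmentation network.

The protocol is plain SGD with momentum 0.9 and a polynomial learning-rate
decay lr(t) = lr0 * (1 - t / T)^power applied per iteration, random
flip-and-crop augmentation per sample, and model selection by the lowest
validation loss.  Defaults follow the published experimental settings
(initial lr 0.002, momentum 0.9, batch 64, 256x256 sub-patches, up to 500
epochs); toy-scale runs override epochs, batch and patch size.

The loss is either the hybrid cross-entropy + edge-aware loss (default,
alpha = beta = 0.5) or plain cross-entropy (``loss_mode="ce"``); validation
uses the same loss as training.  With a fixed seed and a fixed thread count
the whole loss trajectory is bitwise reproducible.
"""

from __future__ import annotations

import csv
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .backbone import EENet, predict_mask
from .losses import LossWeights, hybrid_loss
from .metrics import MetricsReport, evaluate_set
from .nn import SGD
from .synthdata import SegSample, augment
from .tensor import Tensor

__all__ = ["TrainConfig", "TrainResult", "poly_lr", "train", "evaluate"]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters."""

    lr0: float = 0.002
    momentum: float = 0.9
    max_epochs: int = 500
    batch_size: int = 64
    patch: int = 256
    poly_power: float = 0.9
    loss_mode: str = "hybrid"  # "hybrid" or "ce"
    alpha: float = 0.5
    beta: float = 0.5
    seed: int = 0
    device: str = "cpu"
    max_iters: Optional[int] = None  # optional hard cap on total iterations
    augment_train: bool = True  # random flip/crop; disable for pure overfit checks

    def validate(self) -> None:
        if self.lr0 < 0:
            raise ValueError("lr0 must be >= 0")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must lie in [0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1 or self.patch < 1:
            raise ValueError("max_epochs, batch_size and patch must be positive")
        if self.poly_power <= 0:
            raise ValueError("poly_power must be positive")
        if self.loss_mode not in ("hybrid", "ce"):
            raise ValueError("loss_mode must be 'hybrid' or 'ce'")
        if self.loss_mode == "hybrid" and self.alpha + self.beta <= 0:
            raise ValueError("alpha + beta must be positive for the hybrid loss")
        if self.device not in ("cpu", "accelerator"):
            raise ValueError("device must be 'cpu' or 'accelerator'")

    def loss_weights(self) -> LossWeights:
        if self.loss_mode == "ce":
            return LossWeights(alpha=1.0, beta=0.0)
        return LossWeights(alpha=self.alpha, beta=self.beta)


@dataclass
class TrainResult:
    """Best checkpoint (by validation loss) and the training history."""

    best_state: Dict[str, np.ndarray]
    best_epoch: int
    best_val_loss: float
    history: List[Dict[str, float]] = field(default_factory=list)


def poly_lr(lr0: float, iteration: int, max_iter: int, power: float) -> float:
    """Polynomial decay lr0 * (1 - iter/max_iter)^power, clamped at 0."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if iteration >= max_iter:
        return 0.0
    return lr0 * (1.0 - iteration / max_iter) ** power


def _one_hot_batch(masks: np.ndarray, num_classes: int) -> np.ndarray:
    n, h, w = masks.shape
    y = np.zeros((n, num_classes, h, w))
    for c in range(num_classes):
        y[:, c] = masks == c
    return y


def _batch_loss(net: EENet, images: np.ndarray, masks: np.ndarray, weights: LossWeights) -> Tensor:
    probs = net(Tensor(images))
    y = _one_hot_batch(masks, net.config.num_classes)
    return hybrid_loss(probs, Tensor(y), weights)


def _dataset_loss(net: EENet, samples: Sequence[SegSample], weights: LossWeights,
                  batch_size: int) -> float:
    """Mean loss over a dataset at full image size, eval mode, no grad."""
    was_training = net.training
    net.eval()
    total, count = 0.0, 0
    for i in range(0, len(samples), batch_size):
        chunk = samples[i : i + batch_size]
        images = np.stack([s.image for s in chunk])
        masks = np.stack([s.mask for s in chunk])
        loss = _batch_loss(net, images, masks, weights)
        total += float(loss.data) * len(chunk)
        count += len(chunk)
    if was_training:
        net.train()
    return total / count


def train(
    net: EENet,
    train_set: Sequence[SegSample],
    val_set: Sequence[SegSample],
    cfg: TrainConfig,
    history_csv=None,
    log=None,
) -> TrainResult:
    """Optimise ``net`` in place and return the best checkpoint + history.

    Per epoch: seeded shuffle, per-sample random flip/crop augmentation,
    forward, hybrid/CE loss, SGD-momentum step with per-iteration polynomial
    decay; then validation loss in eval mode.  The returned state is the one
    with the minimum validation loss.  Raises ``RuntimeError`` naming the
    epoch if the loss becomes non-finite.
    """
    cfg.validate()
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    weights = cfg.loss_weights()
    n = len(train_set)
    iters_per_epoch = -(-n // cfg.batch_size)
    # the decay schedule spans the full configured run; max_iters is a hard
    # stop (early stopping does not redefine the schedule)
    horizon = cfg.max_epochs * iters_per_epoch
    max_iter = horizon if cfg.max_iters is None else min(horizon, cfg.max_iters)
    opt = SGD(net.parameters(), lr=cfg.lr0, momentum=cfg.momentum)

    result = TrainResult(best_state={}, best_epoch=-1, best_val_loss=np.inf)
    patch = min(cfg.patch, min(min(s.mask.shape) for s in train_set))
    iteration = 0
    net.train()
    for epoch in range(cfg.max_epochs):
        if iteration >= max_iter:
            break
        order = rng.permutation(n)
        epoch_losses = []
        epoch_lr = poly_lr(cfg.lr0, iteration, horizon, cfg.poly_power)
        for start in range(0, n, cfg.batch_size):
            if iteration >= max_iter:
                break
            batch = [train_set[j] for j in order[start : start + cfg.batch_size]]
            if cfg.augment_train:
                batch = [augment(s, patch, seed=int(rng.integers(0, 2**31 - 1))) for s in batch]
            images = np.stack([s.image for s in batch])
            masks = np.stack([s.mask for s in batch])
            loss = _batch_loss(net, images, masks, weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            lr = poly_lr(cfg.lr0, iteration, horizon, cfg.poly_power)
            opt.step(lr)
            epoch_losses.append(float(loss.data))
            iteration += 1
        train_loss = float(np.mean(epoch_losses))
        val_loss = _dataset_loss(net, val_set, weights, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"training diverged: non-finite validation loss at epoch {epoch}")
        record = {
            "epoch": epoch,
            "lr": epoch_lr,
            "train_loss": train_loss,
            "val_loss": val_loss,
        }
        result.history.append(record)
        if log is not None:
            print(
                f"epoch {epoch:4d}  lr {epoch_lr:.6f}  train {train_loss:.5f}  val {val_loss:.5f}",
                file=log if log is not True else sys.stderr,
            )
        if val_loss < result.best_val_loss:
            result.best_val_loss = val_loss
            result.best_epoch = epoch
            result.best_state = net.state_dict()
    if history_csv is not None:
        with open(history_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "lr", "train_loss", "val_loss"])
            writer.writeheader()
            writer.writerows(result.history)
    return result


def evaluate(net: EENet, test_set: Sequence[SegSample]) -> MetricsReport:
    """Predict every test image with :func:`predict_mask` and score it."""
    if not test_set:
        raise ValueError("test set must be non-empty")
    preds = [predict_mask(net, s.image) for s in test_set]
    gts = [s.mask for s in test_set]
    return evaluate_set(preds, gts, image_ids=[s.sample_id for s in test_set])
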