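"""Loss, learning-rate schedules, and the optimization loop.

Training minimizes mean pixelwise binary cross-entropy

    L(p, p_hat) = -(1/(w*h)) * sum_xy [ p log p_hat + (1-p) log(1-p_hat) ]

between the binary ground truth ``p`` and the predicted probability map
``p_hat`` (clamped away from {0, 1} before the logarithms).  The default
optimizer is Adam at an initial learning rate of 1e-3 with cosine decay,
run for 400 epochs in the reference configuration; all of that is
configurable and much smaller settings are used throughout the test suite.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._tensor import SGD, Adam, Tensor, astensor

__all__ = ["MaskPair", "TrainConfig", "bce_loss", "lr_schedule", "train"]


@dataclass
class MaskPair:
    """A binary ground-truth raster and a predicted probability raster."""

    p: np.ndarray
    p_hat: np.ndarray | Tensor

    def __post_init__(self):
        self.p = np.asarray(self.p)
        data = self.p_hat.data if isinstance(self.p_hat, Tensor) else np.asarray(self.p_hat)
        if self.p.shape != data.shape:
            raise ValueError(
                f"mask shapes differ: truth {self.p.shape} vs prediction {data.shape}"
            )
        if not np.isin(self.p, (0, 1)).all():
            raise ValueError("ground-truth mask must be strictly binary (0/1)")
        if data.min() < 0 or data.max() > 1:
            raise ValueError("predicted probabilities must lie in [0, 1]")


@dataclass
class TrainConfig:
    epochs: int = 400
    lr: float = 1e-3
    schedule: str = "cosine"        # cosine | step | constant
    step_every: int = 100           # step schedule: halve every this many epochs
    batch_size: int = 4
    seed: int = 0
    clamp_eps: float = 1e-7
    optimizer: str = "adam"         # adam | sgd
    threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be nonnegative")
        if not (0 < self.clamp_eps < 0.5):
            raise ValueError("clamp_eps must lie in (0, 0.5)")
        if self.schedule not in ("cosine", "step", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def bce_loss(pair: MaskPair, clamp_eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy over the raster (differentiable)."""
    p = Tensor(pair.p.astype(np.float64))
    p_hat = astensor(pair.p_hat).clip(clamp_eps, 1.0 - clamp_eps)
    terms = p * p_hat.log() + (1.0 - p) * (1.0 - p_hat).log()
    return -terms.mean()


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for a given epoch; non-increasing, starts at cfg.lr."""
    if not (0 <= epoch < cfg.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if cfg.schedule == "constant":
        return cfg.lr
    if cfg.schedule == "step":
        return cfg.lr * 0.5 ** (epoch // cfg.step_every)
    # cosine decay to zero over the run
    if cfg.epochs == 1:
        return cfg.lr
    return cfg.lr * 0.5 * (1.0 + math.cos(math.pi * epoch / (cfg.epochs - 1)))


def _stack_dataset(dataset):
    images, masks = [], []
    for item in dataset:
        img, mask = item
        img = np.asarray(img, dtype=np.float64)
        mask = np.asarray(mask)
        if img.ndim == 2:
            img = img[None]
        if mask.ndim == 2:
            mask = mask[None]
        images.append(img)
        masks.append(mask.astype(np.float64))
    return np.stack(images), np.stack(masks)


def train(model, dataset, cfg: TrainConfig, log_path=None,
          progress: bool = False) -> dict:
    """Optimize ``model`` on (image, mask) pairs.

    Returns a dict with the per-epoch mean training loss (``history``), the
    per-epoch learning rate, and the final parameters (also left in the
    model).  Deterministic for a fixed config and seed.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("training dataset is empty")
    X, Y = _stack_dataset(dataset)
    n = X.shape[0]
    params = model.parameters()
    if cfg.optimizer == "adam":
        opt = Adam(params, lr=cfg.lr)
    elif cfg.optimizer == "sgd":
        opt = SGD(params, lr=cfg.lr)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    rng = np.random.default_rng(cfg.seed)
    history, lrs = [], []
    iterator = range(cfg.epochs)
    for epoch in iterator:
        lr = lr_schedule(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            out = model(X[idx])
            pair = MaskPair(Y[idx], out.prob_map)
            loss = bce_loss(pair, clamp_eps=cfg.clamp_eps)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            if lr > 0:
                model.zero_grad()
                loss.backward()
                opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.append(epoch_loss / n)
        lrs.append(lr)
        if progress and (epoch % max(1, cfg.epochs // 10) == 0):
            print(f"epoch {epoch:4d}  lr {lr:.2e}  loss {history[-1]:.5f}")
    result = {"history": history, "lr": lrs,
              "state_dict": model.state_dict(), "config": cfg.to_dict()}
    if log_path is not None:
        write_loss_csv(result, log_path)
    return result


def write_loss_csv(result: dict, path) -> None:
    """Per-epoch loss log: epoch, lr, train_loss."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "lr", "train_loss"])
        for i, (lr, loss) in enumerate(zip(result["lr"], result["history"])):
            writer.writerow([i, f"{lr:.8g}", f"{loss:.8g}"])
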