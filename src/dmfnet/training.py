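"""Training protocol: Adam, staged learning-rate decay, per-epoch checkpoints.

The learning rate is a step schedule — 1e-3 for epochs 1-20, 1e-4 for 21-40,
1e-5 for 41-50, 1e-6 for 51-60 (held beyond 60).  The loss is the mean
squared error between the clean image and the network's prediction; the mean
(rather than sum) convention makes magnitudes resolution-independent, and
any constant factor is absorbed by Adam's adaptive scaling anyway.

A single integer seed drives four independent random streams (weight
initialisation, epoch shuffling, augmentation, noise), so changing one
stage's behaviour never silently shifts another's randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import DMFNet, LayerLedger
from .noise import NoiseSpec, add_noise
from .phantom import DatasetSplit, augment

__all__ = [
    "DEFAULT_LR_SCHEDULE",
    "TrainConfig",
    "TrainState",
    "lr_at_epoch",
    "loss",
    "Adam",
    "train",
]

log = logging.getLogger("dmfnet.train")

#: (last epoch of stage, learning rate) pairs; rate decays x10 after
#: epochs 20, 40 and 50.
DEFAULT_LR_SCHEDULE = ((20, 1e-3), (40, 1e-4), (50, 1e-5), (60, 1e-6))


def lr_at_epoch(epoch: int, schedule=DEFAULT_LR_SCHEDULE) -> float:
    """Learning rate for a 1-based epoch; epochs past the schedule hold the last rate."""
    if epoch < 1:
        raise ValueError(f"epoch must be >= 1, got {epoch}")
    for bound, rate in schedule:
        if epoch <= bound:
            return rate
    return schedule[-1][1]


def loss(clean: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared per-pixel difference between clean and predicted images."""
    clean = np.asarray(clean)
    predicted = np.asarray(predicted)
    if clean.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {clean.shape} vs {predicted.shape}")
    d = clean.astype(np.float64) - predicted.astype(np.float64)
    return float(np.mean(d * d))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 32
    lr_schedule: tuple = DEFAULT_LR_SCHEDULE
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    augment_online: bool = True
    checkpoint_dir: str | None = None

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        rates = [r for _, r in self.lr_schedule]
        if any(b - a <= 0 for a, b in zip(rates[1:], rates[:-1])):
            raise ValueError("learning rates must be strictly decreasing across breakpoints")
        self.noise.validate()


@dataclass
class TrainState:
    epoch: int = 0
    loss_history: list = field(default_factory=list)
    checkpoint_paths: list = field(default_factory=list)
    model: DMFNet | None = None


class Adam:
    """Adam optimiser over a model's (name, array) parameter list."""

    def __init__(self, model: DMFNet, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p) for name, p in model.parameters()}
        self.v = {name: np.zeros_like(p) for name, p in model.parameters()}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        grads = dict(self.model.gradients())
        for name, p in self.model.parameters():
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= (lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)


def _as_image_list(data) -> list:
    if isinstance(data, DatasetSplit):
        return list(data.train)
    return list(data)


def train(config: TrainConfig, data, ledger: LayerLedger | None = None) -> TrainState:
    """Train a DMF-Net on clean images, synthesising noisy inputs on the fly.

    Per batch: each clean image receives a random dihedral transform (if
    ``augment_online``), noise is added per image according to the noise
    spec, the network predicts the denoised batch, and an Adam step is taken
    at the epoch's scheduled rate.  A checkpoint is written after every
    epoch when ``checkpoint_dir`` is set.  Fully deterministic for a given
    config (data order, augmentation, noise and initialisation all derive
    from ``config.seed``).
    """
    config.validate()
    images = _as_image_list(data)
    if not images:
        raise ValueError("training set is empty")
    shapes = {img.shape for img in images}
    if len(shapes) != 1:
        raise ValueError(f"all training images must share a shape, got {sorted(shapes)}")

    ss = np.random.SeedSequence(config.seed)
    s_init, s_shuffle, s_aug, s_noise = ss.spawn(4)
    model = DMFNet(ledger=ledger, seed=np.random.default_rng(s_init))
    opt = Adam(model)
    rng_shuffle = np.random.default_rng(s_shuffle)
    rng_aug = np.random.default_rng(s_aug)
    rng_noise = np.random.default_rng(s_noise)

    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    state = TrainState(model=model)
    n = len(images)
    for epoch in range(1, config.epochs + 1):
        lr = lr_at_epoch(epoch, config.lr_schedule)
        perm = rng_shuffle.permutation(n)
        batch_losses = []
        for bstart in range(0, n, config.batch_size):
            idx = perm[bstart : bstart + config.batch_size]
            clean = []
            for i in idx:
                img = images[i]
                if config.augment_online:
                    img = augment(img, int(rng_aug.integers(2**31)))
                clean.append(img)
            clean = np.stack(clean)[:, None].astype(np.float32)
            noisy = np.stack(
                [add_noise(c[0], config.noise, int(rng_noise.integers(2**31))) for c in clean]
            )[:, None]
            model.zero_grad()
            _, pred = model.forward(noisy, train=True)
            d = pred.astype(np.float64) - clean.astype(np.float64)
            batch_loss = float(np.mean(d * d))
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bstart // config.batch_size + 1}"
                )
            model.backward((2.0 / d.size) * d)
            opt.step(lr)
            batch_losses.append(batch_loss)
        mean_loss = float(np.mean(batch_losses))
        state.loss_history.append(mean_loss)
        state.epoch = epoch
        log.info("epoch %d/%d lr %.1e mean loss %.6f", epoch, config.epochs, lr, mean_loss)
        if ckpt_dir:
            path = ckpt_dir / f"epoch_{epoch}.ckpt"
            model.save(path, extra={"epoch": epoch, "loss": mean_loss})
            state.checkpoint_paths.append(str(path))
    model.release_buffers()  # training-sized activation buffers are large
    return state
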