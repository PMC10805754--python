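"""Training loop for the vessel and tumor-region U-Nets.

The schedule follows the reference recipe: linear warmup to the initial
learning rate over the first epochs, then exponential decay per epoch;
augmentations are random contrast change, additive Gaussian noise and —
for a configurable fraction of samples — a random multiplicative bias
field creating a global intensity gradient. Every augmentation applied is
logged so tests can audit the stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .losses import LossParams, bce_loss, total_loss
from .unet import UNet3D


@dataclass
class TrainingConfig:
    """Hyper-parameters of the training schedule."""

    chunk_size: int = 128
    epochs: int = 150
    lr: float = 1e-4
    warmup_epochs: int = 5
    lr_decay: float = 0.99
    aug_bias_field_prob: float = 0.75
    aug_contrast: bool = True
    aug_gaussian_noise: bool = True
    base_channels: int = 8
    levels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chunk_size % 2 ** (self.levels - 1):
            raise ValueError(
                f"chunk_size {self.chunk_size} not divisible by 2^(levels-1)"
            )
        if not 0 <= self.aug_bias_field_prob <= 1:
            raise ValueError("aug_bias_field_prob must lie in [0, 1]")


def learning_rate(epoch: int, config: TrainingConfig) -> float:
    """Learning rate for a 1-based epoch index.

    Linear ramp over ``warmup_epochs``, then ``lr · decay^(epoch − warmup − 1)``
    so the first post-warmup epoch runs at the full initial rate.
    """
    if epoch <= config.warmup_epochs:
        return config.lr * epoch / config.warmup_epochs
    return config.lr * config.lr_decay ** (epoch - config.warmup_epochs - 1)


@dataclass
class TrainingLog:
    epoch_losses: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    augmentations: list[list[str]] = field(default_factory=list)


def _augment(chunk: np.ndarray, rng: np.random.Generator, config: TrainingConfig) -> tuple[np.ndarray, list[str]]:
    applied = []
    out = chunk.astype(np.float64)
    if config.aug_contrast:
        gamma = rng.uniform(0.7, 1.4)
        lo, hi = out.min(), out.max()
        if hi > lo:
            out = lo + (hi - lo) * ((out - lo) / (hi - lo)) ** gamma
        applied.append(f"contrast:gamma={gamma:.3f}")
    if config.aug_bias_field_prob > 0 and rng.uniform() < config.aug_bias_field_prob:
        g = rng.normal(size=3)
        g /= np.linalg.norm(g) + 1e-12
        axes = [np.linspace(-0.5, 0.5, s) for s in out.shape]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        amp = rng.uniform(0.1, 0.4)
        out = out * (1.0 + amp * (g[0] * zz + g[1] * yy + g[2] * xx))
        applied.append(f"bias_field:amp={amp:.3f}")
    if config.aug_gaussian_noise:
        sd = rng.uniform(0.005, 0.03)
        out = out + rng.normal(scale=sd, size=out.shape)
        applied.append(f"noise:sd={sd:.4f}")
    return out, applied


def train(
    model: UNet3D,
    chunks: list[tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig,
    loss_params: LossParams | None = None,
    loss: str = "total",
) -> tuple[UNet3D, TrainingLog]:
    """Train ``model`` on labeled (image, mask) chunk pairs.

    ``loss`` selects the vessel loss (``"total"``: Dice + clDice + lumen)
    or ``"bce"`` (tumor-region model). Deterministic given ``config.seed``.
    """
    if not chunks:
        raise ValueError("need at least one labeled chunk")
    for img, gt in chunks:
        if img.shape != gt.shape:
            raise ValueError(f"chunk shape mismatch: {img.shape} vs {gt.shape}")
        div = 2 ** (config.levels - 1)
        if any(s % div for s in img.shape):
            raise ValueError(f"chunk shape {img.shape} incompatible with {config.levels} levels")
    loss_params = loss_params or LossParams()
    rng = np.random.default_rng(config.seed)
    opt = ag.Adam(model.parameters(), lr=config.lr)
    log = TrainingLog()

    for epoch in range(1, config.epochs + 1):
        lr = learning_rate(epoch, config)
        opt.lr = lr
        order = rng.permutation(len(chunks))
        epoch_loss = 0.0
        for idx in order:
            img, gt = chunks[idx]
            aug_img, applied = _augment(img, rng, config)
            log.augmentations.append(applied)
            pred = model.forward(aug_img)
            if loss == "bce":
                lval = bce_loss(pred, gt.astype(np.float64))
            else:
                lval = total_loss(pred, gt.astype(np.float64), loss_params)
            opt.zero_grad()
            lval.backward()
            opt.step()
            epoch_loss += lval.item()
        log.epoch_losses.append(epoch_loss / len(chunks))
        log.learning_rates.append(lr)
    return model, log
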