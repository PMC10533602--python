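"""Training with the masked logarithmic loss.

The loss penalises only the beamlines the probe did NOT acquire: acquired
lines are copied bit-exactly by the cubic up-sampler, so their error is
already zero at the input and penalising them is vacuous.  Per image,

    Loss(y, yhat) = sum over masked lines l, depths d of
                    log((|y_ld - yhat_ld| + eps) / k)

on [0, 1]-normalised data with eps = 1e-4 and k = 5/255 (so a pixel whose
error equals 5 grey levels contributes ~0, errors below that contribute
negatively, and the log tempers large-error outliers).  The minimum over
yhat is N_masked * log(eps/k), attained at yhat == y.

``mask_convention`` selects which residue class of the line index is
EXCLUDED from the loss: ``"acquired"`` (default — the loss covers
interpolated lines only) or ``"interpolated"`` (the complementary, literal
mod(l, s) = 0 form).

Optimisation is Adam with a multiplicative per-epoch decay of the learning
rate from ``lr_initial`` down to the floor ``lr_floor`` (reached exactly at
the last epoch), and a fixed epoch budget — no early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .image import USImage
from .metrics import psnr
from .network import CustomWDSR

__all__ = ["LossConfig", "TrainConfig", "masked_log_loss", "masked_log_loss_grad",
           "lr_at_epoch", "train"]


@dataclass(frozen=True)
class LossConfig:
    """Masked logarithmic loss parameters.

    ``s`` is the acquisition stride (the up-sampling factor); ``phase`` the
    index of the first acquired line; ``epsilon`` guards the log at zero
    error; ``k`` sets the curvature (error = k - epsilon contributes 0).
    The log is natural.
    """

    s: int = 2
    phase: int = 0
    epsilon: float = 1e-4
    k: float = 5.0 / 255.0
    mask_convention: str = "acquired"  # residue class EXCLUDED from the loss

    def __post_init__(self) -> None:
        if self.s not in (2, 4):
            raise ValueError(f"s must be 2 or 4, got {self.s}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.k <= self.epsilon:
            raise ValueError("k must exceed epsilon")
        if self.mask_convention not in ("acquired", "interpolated"):
            raise ValueError(f"unknown mask_convention {self.mask_convention!r}")

    def line_mask(self, L: int) -> np.ndarray:
        """Boolean mask over lateral indices: True where the loss applies."""
        l = np.arange(L)
        acquired = (l - self.phase) % self.s == 0
        return ~acquired if self.mask_convention == "acquired" else acquired


@dataclass(frozen=True)
class TrainConfig:
    """Epoch budget, learning-rate schedule, batching and seeding."""

    epochs: int = 200
    lr_initial: float = 1e-3
    lr_floor: float = 1e-6
    batch_size: int = 5  # small batches: many steps/epoch suit the noisy log-loss gradient
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_floor > self.lr_initial:
            raise ValueError("lr floor must not exceed the initial rate")


def _as_batch(images: Sequence[USImage | np.ndarray]) -> np.ndarray:
    arrs = []
    for im in images:
        a = im.to_normalised().pixels if isinstance(im, USImage) else np.asarray(im)
        arrs.append(a)
    return np.stack(arrs)[:, None].astype(np.float32)  # (N, 1, L, D)


def masked_log_loss(y, yhat, cfg: LossConfig) -> float:
    """Masked logarithmic loss of a prediction against its target.

    Accepts single images (L, D) or batches (N, 1, L, D) / (N, L, D);
    batches are reduced by the per-image sum averaged over the batch.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    single = y.ndim == 2
    yb = y[None] if single else y.reshape((-1,) + y.shape[-2:])
    yh = yhat[None] if single else yhat.reshape((-1,) + yhat.shape[-2:])
    mask = cfg.line_mask(yb.shape[-2])
    diff = np.abs(yb[:, mask, :] - yh[:, mask, :])
    per_image = np.log((diff + cfg.epsilon) / cfg.k).sum(axis=(1, 2))
    return float(per_image.sum() if single else per_image.mean())


def masked_log_loss_grad(y, yhat, cfg: LossConfig) -> np.ndarray:
    """Gradient of ``masked_log_loss`` with respect to ``yhat``.

    Zero on every excluded (acquired) line; elsewhere
    -sign(y - yhat) / (|y - yhat| + eps), scaled by 1/N for batches.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    single = y.ndim == 2
    g = np.zeros_like(yhat)
    mask = cfg.line_mask(y.shape[-2])
    sel = (Ellipsis, mask, slice(None))
    diff = yhat[sel] - y[sel]
    g[sel] = np.sign(diff) / (np.abs(diff) + cfg.epsilon)
    if not single:
        n = int(np.prod(y.shape[:-2]))
        g /= n
    return g


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate at a given epoch: geometric decay clipped at the floor.

    Epoch 0 returns ``lr_initial``; the final epoch returns ``lr_floor``
    exactly (single-epoch runs stay at the initial rate).  The sequence is
    monotone non-increasing.
    """
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if cfg.epochs == 1:
        return cfg.lr_initial
    ratio = cfg.lr_floor / cfg.lr_initial
    lr = cfg.lr_initial * ratio ** (epoch / (cfg.epochs - 1))
    return float(max(lr, cfg.lr_floor))


class _Adam:
    def __init__(self, params: List[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: List[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)


def train(
    model: CustomWDSR,
    pairs: Sequence[Tuple[USImage | np.ndarray, USImage | np.ndarray]],
    train_cfg: TrainConfig,
    loss_cfg: LossConfig,
    val_pairs: Sequence[Tuple[USImage | np.ndarray, USImage | np.ndarray]] | None = None,
) -> Tuple[CustomWDSR, Dict[str, List[float]]]:
    """Train in place on (up-sampled input, high-resolution target) pairs.

    Returns the model and a history dict with per-epoch mean training loss
    (``"loss"``), learning rate (``"lr"``) and, when a validation set is
    given, mean validation PSNR in dB on the 0-255 scale (``"val_psnr"``).
    Fully reproducible for a fixed ``train_cfg.seed``.

    Raises on an empty training set and on a non-finite loss (divergence),
    reporting the offending epoch.
    """
    if len(pairs) == 0:
        raise ValueError("empty training set")
    X = _as_batch([p[0] for p in pairs])
    Y = _as_batch([p[1] for p in pairs])
    if X.shape != Y.shape:
        raise ValueError("input/target shapes differ")
    Xv = Yv = None
    if val_pairs:
        Xv = _as_batch([p[0] for p in val_pairs])
        Yv = _as_batch([p[1] for p in val_pairs])

    n = X.shape[0]
    rng = np.random.default_rng(train_cfg.seed)
    opt = _Adam(model.parameters())
    history: Dict[str, List[float]] = {"loss": [], "lr": []}
    if val_pairs:
        history["val_psnr"] = []

    for epoch in range(train_cfg.epochs):
        lr = lr_at_epoch(epoch, train_cfg)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            pred = model.forward(xb)
            loss = masked_log_loss(yb[:, 0], pred[:, 0], loss_cfg)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            grad = masked_log_loss_grad(yb[:, 0], pred[:, 0], loss_cfg)[:, None]
            model.backward(grad.astype(np.float32))
            opt.step(model.gradients(), lr)
            epoch_losses.append(loss)
        history["loss"].append(float(np.mean(epoch_losses)))
        history["lr"].append(lr)
        if val_pairs:
            pv = model.predict_batch(Xv)
            scores = [
                psnr(Yv[i, 0] * 255.0, np.clip(pv[i, 0], 0, 1) * 255.0)
                for i in range(Xv.shape[0])
            ]
            history["val_psnr"].append(float(np.mean(scores)))
    return model, history
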