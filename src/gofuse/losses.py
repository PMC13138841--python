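"""Binary cross-entropy and focal objectives for pairwise matching.

Function prediction is cast as binary classification of protein–term pairs.
Because negatives vastly outnumber positives in some namespaces, the focal
loss down-weights easy examples via the ``(1-ŷ)^γ`` / ``ŷ^γ`` modulating
factors; with γ=0 and the class-balance factor α disabled it reduces exactly
to BCE. "α disabled" means both the α and (1−α) factors are dropped
(treated as 1), not α=0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor

__all__ = ["EPS", "LossConfig", "bce_loss", "focal_loss", "weighted_bce_loss"]

EPS = 1e-7  # clamp for logs


@dataclass(frozen=True)
class LossConfig:
    kind: str = "bce"  # bce | focal | weighted_bce
    gamma: float = 2.0
    alpha: float | None = None  # None = disabled (both class factors 1)
    pos_weight: float = 1.0

    def __post_init__(self):
        if self.kind not in ("bce", "focal", "weighted_bce"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha is not None and not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1) or be None")


def _check(y_hat, y):
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if y_hat.shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} vs {y.shape}")
    return np.clip(y_hat, EPS, 1.0 - EPS), y


def bce_loss(y_hat, y) -> float:
    """Mean binary cross-entropy over a batch of pair probabilities."""
    y_hat, y = _check(y_hat, y)
    return float(-np.mean(y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat)))


def focal_loss(y_hat, y, gamma: float = 2.0, alpha: float | None = None) -> float:
    """Mean focal loss; ``alpha=None`` drops both class-balance factors."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    y_hat, y = _check(y_hat, y)
    a_pos = 1.0 if alpha is None else alpha
    a_neg = 1.0 if alpha is None else 1.0 - alpha
    pos = a_pos * (1.0 - y_hat) ** gamma * y * np.log(y_hat)
    neg = a_neg * y_hat**gamma * (1.0 - y) * np.log(1.0 - y_hat)
    return float(-np.mean(pos + neg))


def weighted_bce_loss(y_hat, y, pos_weight: float = 1.0) -> float:
    """BCE with the positive-class term scaled by ``pos_weight``."""
    y_hat, y = _check(y_hat, y)
    return float(
        -np.mean(pos_weight * y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat))
    )


def loss_tensor(probs: Tensor, y: np.ndarray, cfg: LossConfig) -> Tensor:
    """Differentiable loss on a (B, 1) probability tensor (training path)."""
    yh = probs.clip(EPS, 1.0 - EPS)
    yt = Tensor(np.asarray(y, dtype=np.float64).reshape(-1, 1))
    log_p, log_q = yh.log(), (1.0 - yh).log()
    if cfg.kind == "bce":
        per_pair = yt * log_p + (1.0 - yt) * log_q
    elif cfg.kind == "weighted_bce":
        per_pair = cfg.pos_weight * yt * log_p + (1.0 - yt) * log_q
    else:  # focal
        a_pos = 1.0 if cfg.alpha is None else cfg.alpha
        a_neg = 1.0 if cfg.alpha is None else 1.0 - cfg.alpha
        per_pair = (
            a_pos * (1.0 - yh) ** cfg.gamma * yt * log_p
            + a_neg * yh**cfg.gamma * (1.0 - yt) * log_q
        )
    return -per_pair.mean()
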