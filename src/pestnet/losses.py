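"""Scheduled mixture of label-smoothed cross-entropy and focal loss.

The mixing weight decays linearly over training::

    lambda(t) = lambda_max * (1 - t / T)
    L_total   = lambda * L_CE + (1 - lambda) * L_FL

so early epochs lean on the cross-entropy term for stable learning and the
focus shifts to hard samples (focal term) as training progresses.  Label
smoothing applies to the cross-entropy term only; the focal term keeps
hard targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossSchedule", "FocalConfig", "lambda_at", "ce_smoothed", "focal",
    "total_loss", "MixedLoss", "softmax",
]

_PROB_TOL = 1e-4
_LOG_EPS = 1e-12


@dataclass
class LossSchedule:
    lambda_max: float = 1.0
    total_epochs: int = 1
    current_epoch: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lambda_max <= 1.0:
            raise ValueError("lambda_max must lie in [0, 1]")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")

    @property
    def value(self) -> float:
        return lambda_at(self.current_epoch, self.total_epochs, self.lambda_max)


@dataclass
class FocalConfig:
    gamma: float = 2.0
    class_weights: np.ndarray | None = None

    def __post_init__(self):
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise ValueError("gamma must be finite and >= 0")


def lambda_at(t: int, total_epochs: int, lambda_max: float = 1.0) -> float:
    if total_epochs < 1:
        raise ValueError("total_epochs must be >= 1")
    if t < 0 or t > total_epochs:
        raise ValueError(f"epoch t={t} outside [0, {total_epochs}]")
    return lambda_max * (1.0 - t / total_epochs)


def _validate(probs: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    target = np.atleast_1d(np.asarray(target, dtype=np.int64))
    if probs.shape[0] != target.shape[0]:
        raise ValueError("batch size mismatch between probabilities and targets")
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > _PROB_TOL) or np.any(probs < -_PROB_TOL):
        raise ValueError("probabilities are not normalized distributions")
    if np.any(target < 0) or np.any(target >= probs.shape[1]):
        raise ValueError("target index out of range")
    return probs, target


def ce_smoothed(probs: np.ndarray, target: np.ndarray, epsilon: float = 0.1) -> float:
    """Cross-entropy against the epsilon-smoothed target distribution.

    The target class keeps mass 1 - eps + eps/K and every class receives
    eps/K; equivalently q = (1 - eps) * onehot + eps/K uniform.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    probs, target = _validate(probs, target)
    n, k = probs.shape
    logp = np.log(np.clip(probs, _LOG_EPS, None))
    uniform_term = logp.sum(axis=1) * (epsilon / k)
    target_term = (1.0 - epsilon) * logp[np.arange(n), target]
    return float(-(target_term + uniform_term).mean())


def focal(probs: np.ndarray, target: np.ndarray,
          cfg: FocalConfig | None = None) -> float:
    """Mean of -(1 - p_t)^gamma * log(p_t); gamma=0 is plain cross-entropy."""
    cfg = cfg if cfg is not None else FocalConfig()
    probs, target = _validate(probs, target)
    n = probs.shape[0]
    pt = np.clip(probs[np.arange(n), target], _LOG_EPS, 1.0)
    per_sample = -((1.0 - pt) ** cfg.gamma) * np.log(pt)
    if cfg.class_weights is not None:
        per_sample = per_sample * np.asarray(cfg.class_weights)[target]
    return float(per_sample.mean())


def total_loss(probs: np.ndarray, target: np.ndarray, schedule: LossSchedule,
               cfg: FocalConfig | None = None, epsilon: float = 0.1) -> float:
    lam = schedule.value
    return lam * ce_smoothed(probs, target, epsilon) + \
        (1.0 - lam) * focal(probs, target, cfg)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MixedLoss:
    """Differentiable training objective over raw logits (autodiff path)."""

    def __init__(self, lambda_max: float = 1.0, gamma: float = 2.0,
                 epsilon: float = 0.1):
        self.lambda_max = lambda_max
        self.gamma = gamma
        self.epsilon = epsilon

    def __call__(self, logits: Tensor, target: np.ndarray,
                 t: int, total_epochs: int) -> Tensor:
        lam = lambda_at(t, total_epochs, self.lambda_max)
        n, k = logits.shape
        target = np.asarray(target, dtype=np.int64)
        # stable softmax: subtract the rowwise max as a constant
        shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
        e = shifted.exp()
        probs = e * (e.sum(axis=1, keepdims=True) ** -1.0)
        logp = probs.clip_min(_LOG_EPS).log()
        onehot = np.zeros((n, k), dtype=np.float32)
        onehot[np.arange(n), target] = 1.0
        loss = Tensor(0.0)
        if lam > 0.0:
            smooth = (1.0 - self.epsilon) * onehot + self.epsilon / k
            ce = -(logp * Tensor(smooth)).sum(axis=1).mean()
            loss = loss + lam * ce
        if lam < 1.0:
            pt = (probs * Tensor(onehot)).sum(axis=1)
            fl = -(((1.0 - pt) ** self.gamma) * (logp * Tensor(onehot)).sum(axis=1)).mean()
            loss = loss + (1.0 - lam) * fl
        return loss
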