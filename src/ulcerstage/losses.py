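"""Class-balanced focal loss and the warmup-cosine learning-rate schedule.

The loss reweights cross-entropy by the *effective number of samples*
``(1 - beta) / (1 - beta^{n_y})`` and focuses it on hard examples with the
modulation ``(1 - p_t)^gamma``:

    L_CB = w(n_y) * (1 - p_t)^gamma * (-log p_t)

with beta = 0.9999 and gamma = 3.0 by default.  Class weights are
normalized to mean 1 across classes (switchable) so the loss scale stays
comparable across beta settings.  The schedule is a linear warmup over
``t_warmup`` epochs into a cosine decay from ``eta_max`` to ``eta_min``.

Both pieces are pure functions so they are checkable against closed-form
hand computations; an autodiff variant of the loss feeds training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

EPS_PROB = 1e-12  # probability clamp; below any float32 gradient signal


@dataclass(frozen=True)
class FocalLossConfig:
    beta: float = 0.9999
    gamma: float = 3.0
    class_counts: tuple[int, ...] = field(default=(1, 1, 1, 1, 1, 1))
    normalize_weights: bool = True

    def __post_init__(self):
        if not 0.0 <= self.beta < 1.0:
            raise ValueError(f"beta must be in [0, 1), got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if any(n < 1 for n in self.class_counts):
            raise ValueError(f"all class counts must be >= 1, got {self.class_counts}")


@dataclass(frozen=True)
class ScheduleConfig:
    eta_max: float = 2e-5
    eta_min: float = 0.0
    t_warmup: int = 3
    t_total: int = 50

    def __post_init__(self):
        if not 0.0 <= self.eta_min <= self.eta_max:
            raise ValueError(f"need 0 <= eta_min <= eta_max, got {self.eta_min}, {self.eta_max}")
        if not 0 <= self.t_warmup < self.t_total:
            raise ValueError(f"need 0 <= t_warmup < t_total, got {self.t_warmup}, {self.t_total}")


def class_balance_weight(n_y, beta: float):
    """Effective-number weight ``(1 - beta) / (1 - beta^{n_y})``.

    Strictly decreasing in ``n_y``; equals 1.0 exactly at ``n_y = 1``.
    """
    if beta >= 1.0:
        raise ValueError("beta = 1 divides by zero in the effective-number weight")
    if beta < 0.0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    n = np.asarray(n_y, dtype=float)
    if np.any(n < 1):
        raise ValueError(f"class counts must be >= 1, got {n_y}")
    if beta == 0.0:
        return np.ones_like(n) if n.ndim else 1.0
    out = (1.0 - beta) / (1.0 - beta ** n)
    return out if out.ndim else float(out)


def class_weights(cfg: FocalLossConfig) -> np.ndarray:
    """Per-class weight vector, optionally normalized to mean 1."""
    w = np.asarray([class_balance_weight(n, cfg.beta) for n in cfg.class_counts])
    if cfg.normalize_weights:
        w = w / w.mean()
    return w


def cb_focal_loss(probs: np.ndarray, labels: np.ndarray, cfg: FocalLossConfig) -> float:
    """Mean class-balanced focal loss over samples.

    `probs` holds simplex rows (one per sample), `labels` integer class
    indices.  Zero iff every true-class probability is 1.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    if p.ndim != 2 or len(p) != len(y):
        raise ValueError(f"probs {p.shape} and labels {y.shape} do not align")
    if len(y) == 0:
        raise ValueError("empty batch")
    if np.any((y < 0) | (y >= p.shape[1])):
        raise ValueError("labels outside the class range")
    w = class_weights(cfg)
    p_t = np.clip(p[np.arange(len(y)), y], EPS_PROB, 1.0)
    terms = w[y] * (1.0 - p_t) ** cfg.gamma * (-np.log(p_t))
    return float(terms.mean())


def cb_focal_loss_autodiff(logits: Tensor, targets: np.ndarray,
                           cfg: FocalLossConfig) -> Tensor:
    """Differentiable loss on logits; `targets` may be one-hot or soft rows.

    With soft labels (mixup) the loss is the label-weighted sum of the
    per-class focal terms, which reduces to the hard-label form for
    one-hot rows.
    """
    t = np.asarray(targets, dtype=float)
    if t.ndim == 1:  # integer labels -> one-hot
        onehot = np.zeros((len(t), logits.shape[-1]))
        onehot[np.arange(len(t)), t.astype(int)] = 1.0
        t = onehot
    w = class_weights(cfg)
    p = ad.softmax(logits, axis=-1)
    # clamp via (p + eps) inside the log only; modulation uses raw p
    log_p = ad.log(p + EPS_PROB)
    focal = ad.power(Tensor(1.0) - p, cfg.gamma) if cfg.gamma != 0 else Tensor(np.ones(p.shape))
    terms = Tensor(t * w[None, :]) * focal * (-log_p)
    return terms.sum(axis=-1).mean()


def lr_at(t: float, cfg: ScheduleConfig) -> float:
    """Learning rate at epoch ``t``: linear warmup then cosine decay.

    Continuous at ``t = t_warmup`` (both branches give ``eta_max``);
    fractional ``t`` is supported for testing.
    """
    if not 0 <= t <= cfg.t_total:
        raise ValueError(f"epoch {t} outside [0, {cfg.t_total}]")
    if t < cfg.t_warmup:
        return cfg.eta_max * t / cfg.t_warmup
    frac = (t - cfg.t_warmup) / (cfg.t_total - cfg.t_warmup)
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) * (1.0 + np.cos(np.pi * frac))
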