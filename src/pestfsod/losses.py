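"""Multi-task detection losses.

Classification uses the focal loss, L_cls = -mean_i alpha_t (1-p_t)^gamma
log p_t, which down-weights easy examples (gamma) and re-weights classes
(alpha_t, by default normalised inverse class frequency).  Box regression
uses the smooth-L1 loss on (dx, dy, dw, dh) deltas.  The feature
aggregation regulariser combines a (negative-)entropy term on the
attention weights with an L1 sparsity term on the raw scores.  The total
is the weighted sum

    L_total = L_cls + L_reg + lambda1 * L_agg + lambda2 * L_SCL.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FocalConfig",
    "LossBundle",
    "focal_loss",
    "focal_loss_grad",
    "smooth_l1",
    "smooth_l1_grad",
    "aggregation_loss",
    "aggregation_loss_grad",
    "total_loss",
    "inverse_frequency_alpha",
]

_P_FLOOR = 1e-12


@dataclass
class FocalConfig:
    """Focal-loss knobs: focusing factor gamma and class weights alpha_t."""

    gamma: float = 2.0
    alpha_t: float | np.ndarray = 1.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        a = np.asarray(self.alpha_t, dtype=float)
        if (a <= 0).any():
            raise ValueError("alpha_t must be positive")


def inverse_frequency_alpha(class_counts: dict[int, int], n_classes: int) -> np.ndarray:
    """Per-class weights proportional to 1/count, normalised to mean 1.

    Classes absent from ``class_counts`` get the mean weight.
    """
    alpha = np.ones(n_classes)
    present = [c for c in class_counts if 0 <= c < n_classes]
    if present:
        inv = np.array([1.0 / max(class_counts[c], 1) for c in present])
        inv = inv / inv.mean()
        for c, v in zip(present, inv):
            alpha[c] = v
    return alpha


def _p_true(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if p.ndim != 2 or len(y) != len(p):
        raise ValueError("p must be (N, C) with one label per row")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    pt = p[np.arange(len(y)), y]
    if (pt < _P_FLOOR).any():
        warnings.warn("true-class probability clamped at 1e-12", stacklevel=3)
    return np.clip(pt, _P_FLOOR, 1.0)


def _alpha_for(cfg: FocalConfig, y: np.ndarray) -> np.ndarray:
    a = np.asarray(cfg.alpha_t, dtype=float)
    return a[y] if a.ndim == 1 and a.size > 1 else np.full(len(y), float(a))


def focal_loss(p: np.ndarray, y: np.ndarray, cfg: FocalConfig) -> float:
    """Mean focal loss over samples; gamma=0, alpha=1 is cross-entropy."""
    pt = _p_true(p, y)
    at = _alpha_for(cfg, np.asarray(y, dtype=int).ravel())
    return float(np.mean(-at * (1.0 - pt) ** cfg.gamma * np.log(pt)))


def focal_loss_grad(p: np.ndarray, y: np.ndarray, cfg: FocalConfig) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the probability of the true class only.

    Returned as an (N, C) matrix that is zero off the true class, ready to
    be chained through a softmax backward pass.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    pt = _p_true(p, y)
    at = _alpha_for(cfg, y)
    g = cfg.gamma
    n = len(y)
    loss = float(np.mean(-at * (1.0 - pt) ** g * np.log(pt)))
    if g == 0:
        d = -at / pt
    else:
        d = at * (g * (1.0 - pt) ** (g - 1) * np.log(pt) - (1.0 - pt) ** g / pt)
    grad = np.zeros_like(p)
    grad[np.arange(n), y] = d / n
    return loss, grad


def smooth_l1(t: np.ndarray, v: np.ndarray, beta: float = 1.0) -> float:
    """Smooth-L1 over 4-component box deltas: sum over components, mean
    over boxes.  Quadratic within ``beta`` of zero, linear outside."""
    loss, _ = smooth_l1_grad(t, v, beta)
    return loss


def smooth_l1_grad(t: np.ndarray, v: np.ndarray, beta: float = 1.0) -> tuple[float, np.ndarray]:
    t = np.asarray(t, dtype=float).reshape(-1, 4)
    v = np.asarray(v, dtype=float).reshape(-1, 4)
    if t.shape != v.shape:
        raise ValueError("prediction/target shape mismatch")
    if len(t) == 0:
        return 0.0, np.zeros_like(t)
    x = t - v
    ax = np.abs(x)
    quad = ax < beta
    per = np.where(quad, 0.5 * x**2 / beta, ax - 0.5 * beta)
    grad = np.where(quad, x / beta, np.sign(x)) / len(t)
    return float(per.sum(axis=1).mean()), grad


def aggregation_loss(
    s: np.ndarray, A: np.ndarray, entropy_sign: float = 1.0
) -> tuple[float, float, float]:
    """Attention regulariser terms: (negative-entropy term, sparsity term,
    combined L_agg).

    The combined loss adds ``entropy_sign * mean_i sum_j a_ij log a_ij``
    (the default +1 rewards spread-out attention when minimised, since
    sum a log a is the negative entropy) to the mean L1 norm of the raw
    scores.  0 log 0 is taken as 0.  L_agg can be negative, bounded below
    by -log N_s per row minus nothing from the sparsity term.
    """
    out = aggregation_loss_grad(s, A, entropy_sign)
    return out[0], out[1], out[2]


def aggregation_loss_grad(
    s: np.ndarray, A: np.ndarray, entropy_sign: float = 1.0
) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """As :func:`aggregation_loss`, plus gradients w.r.t. s and A."""
    s = np.asarray(s, dtype=float)
    A = np.asarray(A, dtype=float)
    if s.shape != A.shape:
        raise ValueError("score and weight matrices must share shape")
    if not np.isfinite(s).all():
        raise ValueError("scores contain NaN/Inf")
    if A.size and not np.allclose(A.sum(axis=1), 1.0, atol=1e-4):
        raise ValueError("attention rows must sum to 1")
    n_q = max(A.shape[0], 1)
    logA = np.log(np.clip(A, _P_FLOOR, 1.0))
    neg_entropy = float((A * np.where(A > 0, logA, 0.0)).sum() / n_q)
    sparsity = float(np.abs(s).sum() / n_q)
    l_agg = entropy_sign * neg_entropy + sparsity
    grad_A = entropy_sign * (logA + 1.0) / n_q
    grad_s = np.sign(s) / n_q
    return neg_entropy, sparsity, l_agg, grad_s, grad_A


@dataclass
class LossBundle:
    """Named loss components and their weighted total."""

    l_cls: float
    l_reg: float
    l_agg: float
    l_scl: float
    lambda1: float
    lambda2: float
    l_total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cls": self.l_cls, "reg": self.l_reg, "agg": self.l_agg,
            "scl": self.l_scl, "total": self.l_total,
        }


def total_loss(
    l_cls: float, l_reg: float, l_agg: float, l_scl: float,
    lambda1: float, lambda2: float,
) -> LossBundle:
    """Assemble the weighted multi-task total; aborts on NaN components."""
    parts = {"cls": l_cls, "reg": l_reg, "agg": l_agg, "scl": l_scl}
    for name, v in parts.items():
        if math.isnan(v):
            raise FloatingPointError(f"loss component '{name}' is NaN")
    total = l_cls + l_reg + lambda1 * l_agg + lambda2 * l_scl
    return LossBundle(l_cls, l_reg, l_agg, l_scl, lambda1, lambda2, total)
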