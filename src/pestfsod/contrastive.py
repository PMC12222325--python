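"""Supervised contrastive learning (SCL) on detection RoI embeddings.

Enhanced RoI features pass through a projection head and L2
normalisation onto the unit hypersphere; a supervised contrastive loss
then pulls same-class embeddings together and pushes different-class
embeddings apart:

    L_SCL = sum_i  w_{y_i} / |P(i)|  sum_{p in P(i)}
            -log( exp(z_i . z_p / tau) / sum_{a in A(i)} exp(z_i . z_a / tau) )

where P(i) are the other rows sharing i's label, A(i) all other rows,
tau the temperature, and w_{y_i} = 1/N_{y_i} an inverse class-frequency
weight correcting sample imbalance (w = 1 in the unweighted form).  Rows
without positives contribute nothing (the 1/|P(i)| factor is undefined
for them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._nn import MLP

__all__ = [
    "EmbeddingBatch",
    "SclConfig",
    "ProjectionHead",
    "embed_normalize",
    "embed_backward",
    "supcon_loss",
    "supcon_loss_grad",
]


@dataclass
class EmbeddingBatch:
    """Unit-norm embeddings with labels and reference-set class counts."""

    z: np.ndarray  # (N, d_e), rows on the unit sphere
    labels: np.ndarray  # (N,)
    class_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if len(self.z) != len(self.labels):
            raise ValueError("z and labels length mismatch")
        norms = np.linalg.norm(self.z, axis=1)
        if self.z.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("embedding rows must be unit-norm")
        for c, n in self.class_counts.items():
            if n < 1:
                raise ValueError(f"class {c} has count < 1")


@dataclass
class SclConfig:
    """Contrastive-loss knobs: temperature, weighting, head dimensions."""

    tau: float = 0.2
    weighted: bool = False
    hidden_dim: int = 128
    embed_dim: int = 128

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature must be positive")


class ProjectionHead:
    """One-hidden-layer MLP (D -> hidden -> d_e) used only during training."""

    def __init__(self, rng: np.random.Generator, d_in: int, cfg: SclConfig):
        self.mlp = MLP(rng, [d_in, cfg.hidden_dim, cfg.embed_dim])

    def params(self):
        return self.mlp.params()


def embed_normalize(
    F_enhanced: np.ndarray,
    head: ProjectionHead | None = None,
    labels: np.ndarray | None = None,
    class_counts: dict[int, int] | None = None,
) -> tuple[EmbeddingBatch, dict]:
    """Project features (optionally) and L2-normalise rows to the sphere.

    Returns the batch and a cache for :func:`embed_backward`.  A zero-norm
    projected row is degenerate and raises, naming the row.
    """
    F = np.asarray(F_enhanced, dtype=float)
    if not np.isfinite(F).all():
        raise ValueError("features contain NaN/Inf")
    if head is not None:
        u, mlp_cache = head.mlp.forward(F)
    else:
        u, mlp_cache = F, None
    norms = np.linalg.norm(u, axis=1)
    bad = np.flatnonzero(norms < 1e-12)
    if bad.size:
        raise FloatingPointError(f"zero-norm embedding at row {bad[0]}")
    z = u / norms[:, None]
    n = len(F)
    labels = np.zeros(n, dtype=int) if labels is None else np.asarray(labels, dtype=int)
    batch = EmbeddingBatch(z, labels, class_counts or {})
    cache = {"u": u, "z": z, "norms": norms, "head": head, "mlp_cache": mlp_cache}
    return batch, cache


def embed_backward(cache: dict, grad_z: np.ndarray) -> np.ndarray:
    """Backprop through normalisation (and head); returns grad w.r.t. input."""
    z, norms = cache["z"], cache["norms"]
    g = np.asarray(grad_z, dtype=float)
    gu = (g - np.sum(g * z, axis=1, keepdims=True) * z) / norms[:, None]
    head: ProjectionHead | None = cache["head"]
    if head is None:
        return gu
    return head.mlp.backward(gu, cache["mlp_cache"])


def _row_weights(batch: EmbeddingBatch, cfg: SclConfig, n_pos: np.ndarray) -> np.ndarray:
    """Per-row multiplier w_{y_i}/|P(i)| (zero where |P(i)| = 0)."""
    n = len(batch.z)
    w = np.ones(n)
    if cfg.weighted:
        counts = batch.class_counts
        if not counts:
            raise ValueError("weighted loss requires class_counts")
        w = np.array([1.0 / counts[int(y)] for y in batch.labels])
    with np.errstate(divide="ignore"):
        u = np.where(n_pos > 0, w / np.maximum(n_pos, 1), 0.0)
    return u


def supcon_loss(batch: EmbeddingBatch, cfg: SclConfig) -> float:
    """Supervised contrastive loss (weighted form when cfg.weighted)."""
    loss, _ = supcon_loss_grad(batch, cfg)
    return loss


def supcon_loss_grad(batch: EmbeddingBatch, cfg: SclConfig) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the embeddings z.

    The gradient treats z as free variables; projecting it through
    :func:`embed_backward` keeps rows on the sphere during training.
    """
    z, y = batch.z, batch.labels
    n = len(z)
    if n < 2:
        raise ValueError("contrastive loss needs at least 2 rows")
    pos = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)
    n_pos = pos.sum(axis=1)
    if (n_pos == 0).all():
        warnings.warn("all rows are singleton classes; contrastive loss is 0",
                      stacklevel=2)
        return 0.0, np.zeros_like(z)

    S = (z @ z.T) / cfg.tau
    off = ~np.eye(n, dtype=bool)
    S_masked = np.where(off, S, -np.inf)
    log_den = logsumexp(S_masked, axis=1)  # over A(i)
    u = _row_weights(batch, cfg, n_pos)
    # L = sum_i u_i * (|P(i)| * log_den_i - sum_{p in P(i)} S_ip)
    loss = float(np.sum(u * (n_pos * log_den - (S * pos).sum(axis=1))))

    # dL/dS_ia = u_i * (|P(i)| * softmax_i(a) - [a in P(i)]),  a != i
    soft = np.where(off, np.exp(S_masked - log_den[:, None]), 0.0)
    G = u[:, None] * (n_pos[:, None] * soft - pos.astype(float))
    grad_z = (G @ z + G.T @ z) / cfg.tau
    return loss, grad_z
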