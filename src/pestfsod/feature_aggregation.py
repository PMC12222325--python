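"""Feature aggregation module (FAM): support->query cross-attention.

Pooled support-set RoI features enrich query RoI features through a
single-head scaled dot-product attention:

    Q = F_query W_Q,  K = F_support W_K,  V = F_support W_V
    A = softmax(Q K^T / sqrt(d_k))        (row-stochastic)
    F_agg = A V
    F_enhanced = F_query + alpha * (F_agg W_O)

with learnable projections W_Q/W_K/W_V (no bias), a learnable scalar
``alpha`` gating the residual fusion, and an output projection W_O
(identity-initialised; exactly the identity map when d_k == D).  All
gradients are computed analytically; finite-difference checks live in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Param, kaiming, softmax_rows

__all__ = [
    "FamParams",
    "RoIFeatureBatch",
    "AttentionResult",
    "project_qkv",
    "attention_weights",
    "aggregate_and_fuse",
    "fam_forward",
    "fam_backward",
]


@dataclass
class RoIFeatureBatch:
    """Fixed-size pooled RoI features with labels, for support or query."""

    features: np.ndarray  # (N, D)
    labels: np.ndarray  # (N,)
    role: str = "query"  # "support" | "query"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (N, D) matrix")
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if len(self.labels) != len(self.features):
            raise ValueError("labels length mismatch")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain NaN/Inf")
        if self.role not in ("support", "query"):
            raise ValueError("role must be 'support' or 'query'")

    def __len__(self) -> int:
        return len(self.features)


class FamParams:
    """Learnable FAM parameters: W_Q, W_K, W_V (D -> d_k), W_O (d_k -> D), alpha."""

    def __init__(self, d_feat: int, d_k: int | None = None, alpha_init: float = 0.5,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        d_k = d_feat if d_k is None else d_k
        self.d_feat = d_feat
        self.d_k = d_k
        self.W_Q = Param(kaiming(rng, d_feat, (d_feat, d_k)))
        self.W_K = Param(kaiming(rng, d_feat, (d_feat, d_k)))
        self.W_V = Param(kaiming(rng, d_feat, (d_feat, d_k)))
        if d_k == d_feat:
            self.W_O = Param(np.eye(d_k))
        else:
            self.W_O = Param(kaiming(rng, d_k, (d_k, d_feat)))
        if alpha_init < 0:
            raise ValueError("alpha must be >= 0 at initialisation")
        self.alpha = Param(np.array(float(alpha_init)))

    def params(self) -> list[Param]:
        return [self.W_Q, self.W_K, self.W_V, self.W_O, self.alpha]


@dataclass
class AttentionResult:
    """Scores, row-stochastic weights, aggregated and fused features."""

    scores: np.ndarray  # (N_q, N_s)
    weights: np.ndarray  # (N_q, N_s), rows sum to 1
    F_agg: np.ndarray  # (N_q, d_k)
    F_enhanced: np.ndarray  # (N_q, D)


def project_qkv(
    query: RoIFeatureBatch | np.ndarray,
    support: RoIFeatureBatch | np.ndarray,
    params: FamParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear (bias-free) projections into query/key/value spaces."""
    Fq = query.features if isinstance(query, RoIFeatureBatch) else np.asarray(query, dtype=float)
    Fs = support.features if isinstance(support, RoIFeatureBatch) else np.asarray(support, dtype=float)
    if Fq.shape[1] != params.d_feat or Fs.shape[1] != params.d_feat:
        raise ValueError(
            f"feature dim mismatch: got {Fq.shape[1]}/{Fs.shape[1]}, expected {params.d_feat}"
        )
    return Fq @ params.W_Q.value, Fs @ params.W_K.value, Fs @ params.W_V.value


def attention_weights(Q: np.ndarray, K: np.ndarray, d_k: int) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product scores and their row-softmax weights."""
    Q = np.asarray(Q, dtype=float)
    K = np.asarray(K, dtype=float)
    # d_k is the scaling divisor; it normally equals the key width but the
    # check only requires conformable Q/K and a positive scale
    if d_k < 1 or Q.shape[1] != K.shape[1]:
        raise ValueError("Q/K widths must match and d_k must be >= 1")
    if K.shape[0] == 0:
        raise ValueError("attention is undefined with an empty support set")
    s = (Q @ K.T) / np.sqrt(d_k)
    return s, softmax_rows(s)


def aggregate_and_fuse(
    A: np.ndarray,
    V: np.ndarray,
    F_query: np.ndarray,
    alpha: float,
    W_O: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted support aggregation and residual fusion into the query.

    With ``alpha == 0`` the enhanced features equal the query features
    bit-for-bit.  ``W_O`` maps d_k back to the feature dim; omitted when
    they coincide.
    """
    A = np.asarray(A, dtype=float)
    V = np.asarray(V, dtype=float)
    F_query = np.asarray(F_query, dtype=float)
    F_agg = A @ V
    mapped = F_agg if W_O is None else F_agg @ np.asarray(W_O, dtype=float)
    if mapped.shape != F_query.shape:
        raise ValueError("aggregated features not conformable with query features")
    if alpha == 0:
        return F_agg, F_query.copy()
    return F_agg, F_query + float(alpha) * mapped


def fam_forward(
    F_query: np.ndarray,
    F_support: np.ndarray,
    params: FamParams,
) -> tuple[AttentionResult, dict]:
    """Full FAM pass; returns the result and a cache for :func:`fam_backward`."""
    Q, K, V = project_qkv(F_query, F_support, params)
    s, A = attention_weights(Q, K, params.d_k)
    alpha = float(params.alpha.value)
    F_agg = A @ V
    mapped = F_agg @ params.W_O.value
    F_enh = np.asarray(F_query, dtype=float) + alpha * mapped
    cache = {
        "Fq": np.asarray(F_query, dtype=float),
        "Fs": np.asarray(F_support, dtype=float),
        "Q": Q, "K": K, "V": V, "s": s, "A": A,
        "F_agg": F_agg, "mapped": mapped, "params": params,
    }
    return AttentionResult(s, A, F_agg, F_enh), cache


def fam_backward(
    cache: dict,
    grad_enhanced: np.ndarray,
    grad_scores: np.ndarray | None = None,
    grad_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Backprop through the FAM; accumulates parameter grads in-place.

    ``grad_scores``/``grad_weights`` let loss terms that touch the raw
    scores s or the attention matrix A directly (the aggregation
    regulariser) inject their gradients.  Returns gradients w.r.t. the
    query and support feature matrices.
    """
    p: FamParams = cache["params"]
    Fq, Fs = cache["Fq"], cache["Fs"]
    Q, K, V, A = cache["Q"], cache["K"], cache["V"], cache["A"]
    gE = np.asarray(grad_enhanced, dtype=float)
    alpha = float(p.alpha.value)

    p.alpha.grad += np.sum(gE * cache["mapped"])
    gMapped = alpha * gE
    p.W_O.grad += cache["F_agg"].T @ gMapped
    gAgg = gMapped @ p.W_O.value.T

    gA = gAgg @ V.T
    if grad_weights is not None:
        gA = gA + grad_weights
    gV = A.T @ gAgg
    # softmax backward (row-wise)
    gS = A * (gA - np.sum(gA * A, axis=1, keepdims=True))
    if grad_scores is not None:
        gS = gS + grad_scores
    scale = 1.0 / np.sqrt(p.d_k)
    gQ = gS @ K * scale
    gK = gS.T @ Q * scale

    p.W_Q.grad += Fq.T @ gQ
    p.W_K.grad += Fs.T @ gK
    p.W_V.grad += Fs.T @ gV
    grad_Fq = gE + gQ @ p.W_Q.value.T
    grad_Fs = gK @ p.W_K.value.T + gV @ p.W_V.value.T
    return grad_Fq, grad_Fs
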