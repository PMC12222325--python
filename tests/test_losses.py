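"""Focal, smooth-L1, attention-regulariser and total-loss arithmetic."""

import math

import numpy as np
import pytest

from pestfsod.losses import (FocalConfig, aggregation_loss,
                             aggregation_loss_grad, focal_loss,
                             focal_loss_grad, inverse_frequency_alpha,
                             smooth_l1, smooth_l1_grad, total_loss)


def focal_reference(p, y, gamma, alpha):
    """Independent per-sample loop."""
    total = 0.0
    for i, yi in enumerate(y):
        pt = max(p[i][yi], 1e-12)
        a = alpha[yi] if np.ndim(alpha) else alpha
        total += -a * (1 - pt) ** gamma * math.log(pt)
    return total / len(y)


def smooth_l1_reference(t, v, beta=1.0):
    total = 0.0
    for ti, vi in zip(t, v):
        for x in np.atleast_1d(ti - vi):
            total += 0.5 * x * x / beta if abs(x) < beta else abs(x) - 0.5 * beta
    return total / len(t)


def agg_reference(s, A):
    nq = len(A)
    ent = sum(a * math.log(a) for row in A for a in row if a > 0) / nq
    sp = sum(abs(x) for row in s for x in row) / nq
    return ent, sp, ent + sp


class TestFocal:
    def test_gamma_zero_is_cross_entropy(self):
        p = np.array([[0.5, 0.5]])
        loss = focal_loss(p, [0], FocalConfig(gamma=0.0))
        assert loss == pytest.approx(math.log(2), abs=1e-12)

    def test_confident_prediction_zero(self):
        p = np.array([[1.0, 0.0]])
        for gamma in (0.0, 2.0):
            assert focal_loss(p, [0], FocalConfig(gamma=gamma)) == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_gamma_two(self):
        p = np.array([[0.5, 0.5]])
        loss = focal_loss(p, [0], FocalConfig(gamma=2.0))
        assert loss == pytest.approx(0.25 * math.log(2), abs=1e-12)
        assert loss == pytest.approx(0.17329, abs=1e-5)

    def test_gamma_zero_reduction_random(self, rng):
        p = rng.dirichlet(np.ones(4), size=16)
        y = rng.integers(0, 4, 16)
        ce = -np.mean(np.log(p[np.arange(16), y]))
        assert focal_loss(p, y, FocalConfig(gamma=0.0)) == pytest.approx(ce, rel=1e-10)

    def test_focal_below_cross_entropy(self, rng):
        p = rng.dirichlet(np.ones(5), size=32)
        y = rng.integers(0, 5, 32)
        ce = focal_loss(p, y, FocalConfig(gamma=0.0))
        assert focal_loss(p, y, FocalConfig(gamma=2.0)) <= ce + 1e-12

    def test_reference_oracle_and_gradient(self, rng):
        p = rng.dirichlet(np.ones(3), size=10)
        y = rng.integers(0, 3, 10)
        alpha = inverse_frequency_alpha({0: 5, 1: 3, 2: 2}, 3)
        cfg = FocalConfig(gamma=1.5, alpha_t=alpha)
        loss, grad = focal_loss_grad(p, y, cfg)
        assert loss == pytest.approx(focal_reference(p, y, 1.5, alpha), abs=1e-6)
        eps = 1e-7
        for i in range(3):
            pp = p.copy()
            pp[i, y[i]] += eps
            num = (focal_reference(pp, y, 1.5, alpha) - focal_reference(p, y, 1.5, alpha)) / eps
            assert grad[i, y[i]] == pytest.approx(num, rel=1e-3)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            focal_loss(np.array([[0.4, 0.4]]), [0], FocalConfig())

    def test_clamped_probability_warns(self):
        p = np.array([[0.0, 1.0]])
        with pytest.warns(UserWarning, match="clamped"):
            loss = focal_loss(p, [0], FocalConfig(gamma=0.0))
        assert np.isfinite(loss)


class TestSmoothL1:
    @pytest.mark.parametrize("diff, expected", [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5)])
    def test_single_component_values(self, diff, expected):
        t = np.array([[diff, 0.0, 0.0, 0.0]])
        v = np.zeros((1, 4))
        assert smooth_l1(t, v) == pytest.approx(expected, abs=1e-12)

    def test_exact_match_zero(self, rng):
        t = rng.normal(size=(5, 4))
        assert smooth_l1(t, t) == 0.0

    def test_c1_continuity_at_beta(self):
        beta = 1.0
        for x in (beta - 1e-6, beta + 1e-6):
            t = np.array([[x, 0, 0, 0]])
            _, g = smooth_l1_grad(t, np.zeros((1, 4)), beta)
            assert g[0, 0] == pytest.approx(1.0, abs=2e-6)
        lo = smooth_l1(np.array([[beta - 1e-6, 0, 0, 0]]), np.zeros((1, 4)), beta)
        hi = smooth_l1(np.array([[beta + 1e-6, 0, 0, 0]]), np.zeros((1, 4)), beta)
        assert hi - lo == pytest.approx(2e-6, rel=1e-3)

    def test_reference_oracle_and_gradient(self, rng):
        t = rng.normal(scale=2, size=(7, 4))
        v = rng.normal(scale=2, size=(7, 4))
        loss, grad = smooth_l1_grad(t, v)
        assert loss == pytest.approx(smooth_l1_reference(t, v), abs=1e-6)
        eps = 1e-7
        tp = t.copy()
        tp[2, 1] += eps
        num = (smooth_l1_reference(tp, v) - smooth_l1_reference(t, v)) / eps
        assert grad[2, 1] == pytest.approx(num, rel=1e-3)


class TestAggregationLoss:
    def test_one_hot_rows_zero(self):
        A = np.eye(3)
        s = np.zeros((3, 3))
        ent, sp, l_agg = aggregation_loss(s, A)
        assert ent == 0.0 and sp == 0.0 and l_agg == 0.0

    def test_uniform_rows_negative_log_ns(self):
        A = np.full((2, 4), 0.25)
        s = np.zeros((2, 4))
        ent, sp, l_agg = aggregation_loss(s, A)
        assert l_agg == pytest.approx(-math.log(4), abs=1e-12)
        assert l_agg == pytest.approx(-1.3863, abs=1e-4)

    def test_sparsity_term(self):
        s = np.array([[1.0, -1.0]])
        A = np.full((1, 2), 0.5)
        _, sp, _ = aggregation_loss(s, A)
        assert sp == pytest.approx(2.0, abs=1e-12)

    def test_entropy_bounds(self, rng):
        for _ in range(10):
            raw = rng.normal(size=(4, 6))
            A = np.exp(raw) / np.exp(raw).sum(axis=1, keepdims=True)
            ent, sp, _ = aggregation_loss(raw, A)
            assert -math.log(6) - 1e-9 <= ent <= 1e-9
            assert sp >= 0

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            aggregation_loss(np.zeros((1, 2)), np.array([[0.7, 0.7]]))

    def test_sign_switch(self):
        A = np.full((1, 4), 0.25)
        s = np.zeros((1, 4))
        _, _, verbatim = aggregation_loss(s, A, entropy_sign=1.0)
        _, _, flipped = aggregation_loss(s, A, entropy_sign=-1.0)
        assert verbatim == -flipped

    def test_reference_oracle_and_gradients(self, rng):
        raw = rng.normal(size=(5, 7))
        A = np.exp(raw) / np.exp(raw).sum(axis=1, keepdims=True)
        ent, sp, l_agg, gs, gA = aggregation_loss_grad(raw, A)
        r_ent, r_sp, r_tot = agg_reference(raw, A)
        assert ent == pytest.approx(r_ent, abs=1e-6)
        assert sp == pytest.approx(r_sp, abs=1e-6)
        assert l_agg == pytest.approx(r_tot, abs=1e-6)
        eps = 1e-7
        A2 = A.copy()
        A2[1, 2] += eps
        num = (agg_reference(raw, A2)[0] - r_ent) / eps
        assert gA[1, 2] == pytest.approx(num, rel=1e-3)
        s2 = raw.copy()
        s2[0, 3] += eps
        num = (agg_reference(s2, A)[1] - r_sp) / eps
        assert gs[0, 3] == pytest.approx(num, rel=1e-3)


class TestTotalLoss:
    def test_zero_components(self):
        b = total_loss(0, 0, 0, 0, 0.5, 0.5)
        assert b.l_total == 0.0

    def test_arithmetic_identity(self):
        b = total_loss(1.0, 2.0, 3.0, 4.0, 0.5, 0.5)
        assert b.l_total == pytest.approx(6.5, abs=1e-12)
        recomputed = b.l_cls + b.l_reg + b.lambda1 * b.l_agg + b.lambda2 * b.l_scl
        assert abs(b.l_total - recomputed) <= 1e-9 * max(abs(b.l_total), 1)

    def test_ablation_limit(self):
        b = total_loss(1.2, 0.7, 5.0, 9.0, 0.0, 0.0)
        assert b.l_total == pytest.approx(1.9, abs=1e-12)

    def test_nan_aborts_with_name(self):
        with pytest.raises(FloatingPointError, match="'agg'"):
            total_loss(1.0, 1.0, float("nan"), 0.0, 1.0, 1.0)


def test_inverse_frequency_alpha_normalised():
    alpha = inverse_frequency_alpha({0: 10, 1: 1}, 2)
    assert alpha[1] > alpha[0]
    assert alpha.mean() == pytest.approx(1.0)
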