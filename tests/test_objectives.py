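"""Closed-form and property checks for the loss components."""

import autograd
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import medcss as m
from medcss.objectives import CodingRateParams


def _direct_js_bits(p, q, eps=1e-12):
    """Independent two-term KL summation oracle, base-2."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    mid = (p + q) / 2

    def kl(a, b):
        return float(np.sum(a * (np.log(a + eps) - np.log(b + eps))) / np.log(2))

    return 0.5 * kl(p, mid) + 0.5 * kl(q, mid)


class TestCovariance:
    def test_two_point_batch(self):
        np.testing.assert_allclose(m.covariance([[-1.0], [1.0]]), [[1.0]], atol=1e-12)

    def test_single_row_is_zero(self):
        np.testing.assert_allclose(m.covariance([[3.0, -2.0, 5.0]]), np.zeros((3, 3)))

    def test_constant_rows_are_zero(self):
        F = np.tile([1.5, -0.5], (6, 1))
        np.testing.assert_allclose(m.covariance(F), np.zeros((2, 2)), atol=1e-12)

    def test_symmetric_psd(self, rng):
        F = rng.normal(size=(10, 4))
        S = m.covariance(F)
        np.testing.assert_allclose(S, S.T, atol=1e-8)
        assert np.linalg.eigvalsh(S).min() > -1e-8

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            m.covariance([[np.nan, 1.0]])


class TestCodingRate:
    def test_zero_for_constant_features(self):
        assert m.coding_rate(np.zeros((5, 3)), CodingRateParams(alpha=2.0, jitter=0.0)) == 0.0

    def test_two_point_closed_form(self):
        r = m.coding_rate(np.array([[-1.0], [1.0]]), CodingRateParams(alpha=1.0, jitter=0.0))
        assert r == pytest.approx(0.5 * np.log(2), abs=1e-9)

    @pytest.mark.parametrize("d", [1, 2, 3, 5])
    @pytest.mark.parametrize("sigma2,alpha", [(1.0, 1.0), (0.25, 2.0), (4.0, 0.5)])
    def test_isotropic_closed_form(self, d, sigma2, alpha):
        # construct a batch with exactly isotropic covariance sigma2 * I_d
        B = 2 * d
        F = np.concatenate([np.eye(d), -np.eye(d)]) * np.sqrt(sigma2 * d)
        assert np.allclose(m.covariance(F), sigma2 * np.eye(d))
        r = m.coding_rate(F, CodingRateParams(alpha=alpha, jitter=0.0))
        # brute-force determinant oracle at small d
        oracle = 0.5 * np.log(np.linalg.det(np.eye(d) + alpha * sigma2 * np.eye(d)))
        assert r == pytest.approx((d / 2) * np.log(1 + alpha * sigma2), abs=1e-9)
        assert r == pytest.approx(oracle, abs=1e-9)

    def test_monotone_in_alpha(self, rng):
        F = rng.normal(size=(6, 4))
        rates = [m.coding_rate(F, CodingRateParams(alpha=a)) for a in (0.5, 1.0, 2.0)]
        assert rates[0] < rates[1] < rates[2]

    def test_rotation_invariance(self, rng):
        F = rng.normal(size=(12, 8))
        Q = np.linalg.qr(rng.normal(size=(8, 8)))[0]
        r1 = m.coding_rate(F, CodingRateParams(alpha=1.3))
        r2 = m.coding_rate(F @ Q, CodingRateParams(alpha=1.3))
        assert r2 == pytest.approx(r1, abs=1e-6)

    @pytest.mark.parametrize("B,d", [(4, 9), (9, 4)])
    def test_gram_duality(self, rng, B, d):
        """Primal d x d and dual B x B forms agree for d > B and d < B."""
        F = rng.normal(size=(B, d))
        params = CodingRateParams(alpha=0.7, jitter=0.0)
        r = m.coding_rate(F, params)
        centered = F - F.mean(axis=0)
        primal = 0.5 * np.linalg.slogdet(np.eye(d) + 0.7 / B * centered.T @ centered)[1]
        dual = 0.5 * np.linalg.slogdet(np.eye(B) + 0.7 / B * centered @ centered.T)[1]
        assert primal == pytest.approx(dual, abs=1e-9)
        assert r == pytest.approx(primal, abs=1e-6)

    def test_row_permutation_invariance(self, rng):
        F = rng.normal(size=(7, 3))
        perm = rng.permutation(7)
        assert m.coding_rate(F[perm]) == pytest.approx(m.coding_rate(F), abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(10):
            F = rng.normal(size=rng.integers(1, 8, size=2))
            assert m.coding_rate(F) >= 0.0


class TestCrrLoss:
    def test_hinge_inactive_when_deeper_more_compressed(self):
        # scaled isotropic features: R grows with scale, so R(F3) < R(F4)
        F3 = np.array([[-0.5], [0.5]])
        F4 = np.array([[-2.0], [2.0]])
        assert m.crr_loss(F3, F4) == 0.0

    def test_active_hinge_value(self):
        F3 = np.array([[-1.0], [1.0]])
        F4 = np.zeros((2, 1))
        val = m.crr_loss(F3, F4, CodingRateParams(alpha=1.0, jitter=0.0))
        assert val == pytest.approx(0.5 * np.log(2), abs=1e-9)

    def test_identical_features_zero(self, rng):
        F = rng.normal(size=(5, 3))
        assert m.crr_loss(F, F) == 0.0

    def test_per_dim_normalization(self):
        # raw: R(F3)=ln(2)/2 > R(F4)=0 -> active; per-dim divides by d
        F3 = np.array([[-1.0, 0.0], [1.0, 0.0]])
        F4 = np.zeros((2, 4))
        params = CodingRateParams(alpha=1.0, jitter=0.0)
        raw = m.crr_loss(F3, F4, params)
        normalized = m.crr_loss(F3, F4, params, per_dim=True)
        assert raw == pytest.approx(0.5 * np.log(2), abs=1e-9)
        assert normalized == pytest.approx(raw / 2, abs=1e-9)

    def test_batch_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            m.crr_loss(rng.normal(size=(4, 2)), rng.normal(size=(5, 2)))

    def test_gradient_matches_finite_differences(self, rng):
        """Autodiff gradient of the active hinge vs central differences."""
        F3 = rng.normal(size=(4, 3)) * 3.0
        F4 = rng.normal(size=(4, 3)) * 0.01  # hinge active: R(F3) >> R(F4)
        params = CodingRateParams(alpha=1.0, jitter=0.0)
        assert m.crr_loss(F3, F4, params) > 0
        g = autograd.grad(lambda A: m.crr_loss(A, F4, params))(F3)
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                Fp, Fm = F3.copy(), F3.copy()
                Fp[i, j] += eps
                Fm[i, j] -= eps
                fd = (m.crr_loss(Fp, F4, params) - m.crr_loss(Fm, F4, params)) / (2 * eps)
                assert g[i, j] == pytest.approx(fd, abs=1e-4)


class TestBatchDistribution:
    def test_uniform_for_zero_row(self):
        np.testing.assert_allclose(m.batch_distribution(np.zeros((1, 4))), np.full(4, 0.25))

    def test_averaging_identical_rows(self, rng):
        row = rng.normal(size=(1, 6))
        np.testing.assert_allclose(
            m.batch_distribution(np.tile(row, (2, 1))), m.batch_distribution(row), atol=1e-12
        )

    def test_softmax_hand_value(self):
        np.testing.assert_allclose(
            m.batch_distribution(np.array([[np.log(3), 0.0]])), [0.75, 0.25], atol=1e-12
        )

    def test_sums_to_one_and_row_permutation_invariant(self, rng):
        H = rng.normal(size=(8, 5))
        p = m.batch_distribution(H)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(m.batch_distribution(H[rng.permutation(8)]), p, atol=1e-12)

    def test_single_coordinate_rejected(self):
        with pytest.raises(ValueError):
            m.batch_distribution(np.zeros((3, 1)))


class TestJsDivergence:
    def test_identical_is_zero(self):
        assert m.js_divergence([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_is_one_bit(self):
        assert m.js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0, abs=1e-9)

    def test_half_vs_point_mass(self):
        assert m.js_divergence([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.311278, abs=1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_matches_direct_summation_symmetric_bounded(self, a, b):
        k = min(len(a), len(b))
        p = np.array(a[:k]) / np.sum(a[:k])
        q = np.array(b[:k]) / np.sum(b[:k])
        v = m.js_divergence(p, q)
        assert v == pytest.approx(_direct_js_bits(p, q), abs=1e-9)
        assert v == pytest.approx(m.js_divergence(q, p), abs=1e-12)
        assert -1e-12 <= v <= 1.0 + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.js_divergence([0.5, 0.5], [0.2, 0.3, 0.5])


class TestAlignmentLoss:
    def test_identical_heads_zero(self, rng):
        H = rng.normal(size=(4, 6))
        assert m.alignment_loss(H, H) == pytest.approx(0.0, abs=1e-12)

    def test_bounded(self, rng):
        for _ in range(5):
            v = m.alignment_loss(rng.normal(size=(3, 4)), rng.normal(size=(5, 4)))
            assert 0.0 <= v <= 1.0

    def test_near_degenerate_softmaxes(self):
        v = m.alignment_loss(np.array([[20.0, -20.0]]), np.array([[-20.0, 20.0]]))
        assert v == pytest.approx(1.0, abs=1e-4)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            m.alignment_loss(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)))


class TestTotalLoss:
    def test_reduces_to_supervised_at_zero_weights(self):
        b = m.total_loss(0.7, 0.2, 0.1, 0.0, 0.0)
        assert b.total == 0.7

    def test_plain_sum(self):
        assert m.total_loss(0.5, 0.4, 0.3, 1.0, 1.0).total == pytest.approx(1.2, abs=1e-12)

    def test_weighted_combination(self):
        b = m.total_loss(1.0, 0.5, 0.2, 0.1, 0.01)
        assert b.total == pytest.approx(1.052, abs=1e-9)
        assert b.total == pytest.approx(
            b.sup + b.lambda_align * b.align + b.lambda_crr * b.crr, abs=1e-9
        )

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            m.total_loss(1.0, 0.1, 0.1, -0.1, 0.0)
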