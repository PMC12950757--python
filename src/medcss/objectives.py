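"""Loss components for hierarchical feature-consistency training.

This module holds the mathematical core of the framework: the coding rate
of a feature batch, the coding-rate-reduction (CRR) hinge that asks deeper
features to be *more compressed* than intermediate ones, the Jensen-Shannon
alignment loss between the empirical distributions of two projection heads,
and the joint objective that combines them with a supervised task loss.

All functions are written against ``autograd.numpy`` so that every loss is
differentiable end-to-end with reverse-mode autodiff; plain numpy arrays
pass through unchanged when no gradient is requested.

Conventions
-----------
* A feature batch is a real matrix ``F`` of shape ``(B, d)`` — B samples,
  d feature coordinates.
* The coding rate is reported in nats (natural log); the JS divergence in
  bits (base-2 log), so the alignment loss is bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

__all__ = [
    "CodingRateParams",
    "LossBundle",
    "covariance",
    "coding_rate",
    "crr_loss",
    "batch_distribution",
    "js_divergence",
    "alignment_loss",
    "total_loss",
]

_JS_EPS = 1e-12


@dataclass(frozen=True)
class CodingRateParams:
    """Parameters of the coding-rate functional.

    Parameters
    ----------
    alpha : float
        Sensitivity to feature variance; scales the covariance inside the
        log-determinant. Must be positive.
    jitter : float
        Small non-negative diagonal term added before factorization for
        numerical stability. Capped at 1e-4.
    """

    alpha: float = 1.0
    jitter: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (0 <= self.jitter <= 1e-4):
            raise ValueError(f"jitter must be in [0, 1e-4], got {self.jitter}")


@dataclass(frozen=True)
class LossBundle:
    """All components of the joint objective for one step.

    ``sup`` and ``crr`` are in nats, ``align`` in bits (bounded by 1);
    ``total = sup + lambda_align * align + lambda_crr * crr``.
    """

    sup: float
    align: float
    crr: float
    lambda_align: float
    lambda_crr: float
    total: float


def _as_feature_matrix(F, name: str = "F"):
    F = F if isinstance(F, anp.numpy_boxes.ArrayBox) else np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise ValueError(f"{name} must be 2-D (B, d), got shape {np.shape(F)}")
    if not isinstance(F, anp.numpy_boxes.ArrayBox) and not np.all(np.isfinite(F)):
        raise ValueError(f"{name} contains non-finite entries")
    return F


def covariance(F):
    """Batch covariance ``Sigma = (1/B) (F - mean)^T (F - mean)``.

    The normalization is 1/B (a population covariance over the batch), not
    the unbiased 1/(B-1): a single-row batch therefore has exactly zero
    covariance. The result is symmetric positive semidefinite.
    """
    F = _as_feature_matrix(F)
    B = F.shape[0]
    centered = F - anp.mean(F, axis=0, keepdims=True)
    return anp.matmul(anp.transpose(centered), centered) / B


def coding_rate(F, params: CodingRateParams = CodingRateParams()):
    """Coding rate ``R(F) = 1/2 log det(I + alpha * Sigma_F)`` in nats.

    Measures the log-volume (redundancy) of the feature batch's covariance
    ellipsoid. Computed from a Cholesky factorization of
    ``I + alpha * Sigma + jitter * I`` — never from the raw determinant —
    so it is overflow-safe and differentiable. When ``d > B`` the dual
    ``B x B`` Gram form ``I + (alpha/B) Fc Fc^T`` is used instead; the two
    share their non-unit eigenvalues, so the value is identical.
    """
    F = _as_feature_matrix(F)
    B, d = F.shape
    centered = F - anp.mean(F, axis=0, keepdims=True)
    if d > B:
        M = anp.matmul(centered, anp.transpose(centered)) * (params.alpha / B)
        n = B
    else:
        M = anp.matmul(anp.transpose(centered), centered) * (params.alpha / B)
        n = d
    M = M + anp.eye(n) * (1.0 + params.jitter)
    try:
        L = anp.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - jittered PSD matrix
        raise FloatingPointError(
            f"Cholesky factorization of I + alpha*Sigma failed even with "
            f"jitter={params.jitter} (alpha={params.alpha}, shape {np.shape(F)})"
        ) from exc
    # axis order chosen for autograd's diagonal VJP support
    return anp.sum(anp.log(anp.diagonal(L, axis1=-1, axis2=-2)))


def crr_loss(F3, F4, params: CodingRateParams = CodingRateParams(), per_dim: bool = False):
    """Coding-rate-reduction hinge ``max(0, R(F3) - R(F4))``.

    Penalizes *information inflation* along the hierarchy: it is zero
    whenever the deeper features ``F4`` are already at least as compressed
    as the intermediate ``F3``. The feature dimensions may differ; the
    batch sizes must match. With ``per_dim=True`` each rate is divided by
    its feature dimension before the comparison, compensating for the
    wider deep stages; the default compares the raw rates.
    """
    F3 = _as_feature_matrix(F3, "F3")
    F4 = _as_feature_matrix(F4, "F4")
    if F3.shape[0] != F4.shape[0]:
        raise ValueError(
            f"F3 and F4 must come from the same batch: B={F3.shape[0]} vs {F4.shape[0]}"
        )
    r3 = coding_rate(F3, params)
    r4 = coding_rate(F4, params)
    if per_dim:
        r3, r4 = r3 / F3.shape[1], r4 / F4.shape[1]
    return anp.maximum(0.0, r3 - r4)


def batch_distribution(H):
    """Empirical categorical distribution of a projection batch.

    Each row of ``H`` is softmax-normalized into a distribution over its
    ``d`` coordinates; the batch average of those per-sample distributions
    is returned. This is the differentiable, batch-size-robust construction
    used to compare projection heads via JS divergence.
    """
    H = _as_feature_matrix(H, "H")
    if H.shape[1] < 2:
        raise ValueError(f"need at least 2 feature coordinates, got d={H.shape[1]}")
    shifted = H - anp.max(H, axis=1, keepdims=True)
    e = anp.exp(shifted)
    p = e / anp.sum(e, axis=1, keepdims=True)
    return anp.mean(p, axis=0)


def js_divergence(p, q):
    """Jensen-Shannon divergence in bits, bounded in [0, 1].

    ``JS(p||q) = KL(p||m)/2 + KL(q||m)/2`` with ``m = (p+q)/2`` and base-2
    logarithms, epsilon-smoothed inside the logs. Symmetric, zero iff the
    distributions coincide (up to smoothing).
    """
    p, q = _check_prob_pair(p, q)
    m = (p + q) / 2.0
    return 0.5 * _kl_bits(p, m) + 0.5 * _kl_bits(q, m)


def _kl_bits(p, m):
    return anp.sum(p * (anp.log(p + _JS_EPS) - anp.log(m + _JS_EPS))) / anp.log(2.0)


def _check_prob_pair(p, q):
    def prep(v, name):
        boxed = isinstance(v, anp.numpy_boxes.ArrayBox)
        v = v if boxed else np.asarray(v, dtype=float)
        if v.ndim != 1:
            raise ValueError(f"{name} must be a 1-D probability vector")
        if not boxed:
            if np.any(v < -1e-12):
                raise ValueError(f"{name} has negative entries")
            if abs(float(np.sum(v)) - 1.0) > 1e-6:
                raise ValueError(f"{name} does not sum to 1 (sum={float(np.sum(v))})")
        return v

    p = prep(p, "p")
    q = prep(q, "q")
    if p.shape[0] != q.shape[0]:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    return p, q


def alignment_loss(H3, H4):
    """Cross-level alignment loss: JS between the empirical distributions
    of the two projection heads, in bits.

    ``H3`` and ``H4`` must share the projection dimension (the heads map
    into a common latent space); batch sizes may differ in principle since
    each batch is first reduced to one categorical distribution.
    """
    H3 = _as_feature_matrix(H3, "H3")
    H4 = _as_feature_matrix(H4, "H4")
    if H3.shape[1] != H4.shape[1]:
        raise ValueError(
            f"projection dimensions differ: {H3.shape[1]} vs {H4.shape[1]}"
        )
    return js_divergence(batch_distribution(H3), batch_distribution(H4))


def total_loss(sup, align, crr, lambda_align, lambda_crr) -> LossBundle:
    """Joint objective ``L = L_sup + lambda_align*L_align + lambda_crr*L_crr``."""
    if lambda_align < 0 or lambda_crr < 0:
        raise ValueError("loss weights must be non-negative")
    sup, align, crr = float(sup), float(align), float(crr)
    total = sup + lambda_align * align + lambda_crr * crr
    return LossBundle(
        sup=sup,
        align=align,
        crr=crr,
        lambda_align=float(lambda_align),
        lambda_crr=float(lambda_crr),
        total=total,
    )
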