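"""Multivariate normal rectangle probabilities for the parametric tests.

Dimension 1 is the normal CDF; dimension 2 uses the exact Owen's-T
representation of the bivariate normal CDF (vectorised, deterministic,
accurate to machine precision, with the degenerate ``rho = +/-1`` limits
handled explicitly); dimension >= 3 falls back to
``scipy.stats.multivariate_normal.cdf``, which is deterministic across calls
for a fixed input in the quadrature configuration used here.
"""

from __future__ import annotations

import numpy as np
from scipy.special import owens_t
from scipy.stats import multivariate_normal, norm

__all__ = ["bvn_cdf", "joint_cdf", "prob_none_below"]


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorised over ``h`` and ``k``.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if rho >= 1.0 - 1e-12:
        return norm.cdf(np.minimum(h, k))
    if rho <= -1.0 + 1e-12:
        return np.maximum(0.0, norm.cdf(h) + norm.cdf(k) - 1.0)
    s = np.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = np.where(h != 0.0, (k - rho * h) / (h * s), np.inf * np.sign(k))
        ak = np.where(k != 0.0, (h - rho * k) / (k * s), np.inf * np.sign(h))
    # at the origin both ratios are 0/0; the closed form there is known
    both_zero = (h == 0.0) & (k == 0.0)
    ah = np.where(both_zero | np.isnan(ah), 0.0, ah)
    ak = np.where(both_zero | np.isnan(ak), 0.0, ak)
    beta = np.where((h * k > 0) | ((h * k == 0) & (h + k >= 0)), 0.0, 0.5)
    out = 0.5 * (norm.cdf(h) + norm.cdf(k)) - owens_t(h, ah) - owens_t(k, ak) - beta
    out = np.where(both_zero, 0.25 + np.arcsin(rho) / (2.0 * np.pi), out)
    # infinite limits short-circuit the Owen terms
    out = np.where(np.isneginf(h) | np.isneginf(k), 0.0, out)
    out = np.where(np.isposinf(h), norm.cdf(k), out)
    out = np.where(np.isposinf(k) & np.isfinite(h), norm.cdf(h), out)
    return np.clip(out, 0.0, 1.0)


def joint_cdf(upper: np.ndarray, corr: np.ndarray) -> float:
    """P(Z_1 <= upper_1, ..., Z_d <= upper_d) for correlation matrix ``corr``."""
    upper = np.asarray(upper, dtype=float)
    d = upper.shape[0]
    if d == 1:
        return float(norm.cdf(upper[0]))
    if d == 2:
        return float(bvn_cdf(upper[0], upper[1], float(corr[0, 1])))
    if np.any(np.isneginf(upper)):
        return 0.0
    return float(
        multivariate_normal.cdf(
            upper, mean=np.zeros(d), cov=corr, allow_singular=True
        )
    )


def prob_none_below(thresholds: np.ndarray, corr: np.ndarray) -> float:
    """P(P_j > t_j for all j) for one-sided normal p-values ``P_j = 1 - Phi(Z_j)``.

    ``P_j > t_j`` is ``Z_j < Phi^{-1}(1 - t_j)``; a threshold of 0 imposes no
    constraint, a threshold of 1 forces the event to fail.
    """
    t = np.clip(np.asarray(thresholds, dtype=float), 0.0, 1.0)
    upper = norm.ppf(1.0 - t)
    return joint_cdf(upper, np.asarray(corr, dtype=float))
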