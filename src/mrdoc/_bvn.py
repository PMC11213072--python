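"""Bivariate standard-normal rectangle and orthant probabilities.

The liability-threshold likelihood of a twin pair reduces to rectangle
probabilities of a correlated bivariate normal.  These are computed from
Owen's T function, which gives absolute accuracy near machine precision and
vectorizes over thresholds (the correlation is constant within a zygosity
group, so a scalar ``rho`` suffices).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "bivariate_normal_orthant"]

# Beyond |h| = 40 the marginal normal CDF is exactly 0/1 in double precision,
# so clipping infinite or huge bounds there is lossless.
_CLIP = 40.0


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Vectorized over ``h`` and ``k``; ``rho`` is scalar.  Uses the classical
    Owen's T decomposition; exact zero bounds are perturbed by 1e-15, which
    changes the result by less than the perturbation (the CDF has bounded
    derivative) while keeping the formula branch-free.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.isnan(h).any() or np.isnan(k).any() or np.isnan(rho):
        raise ValueError("NaN bounds or correlation in bivariate normal CDF")
    h, k = np.broadcast_arrays(h, k)
    rho = float(min(max(rho, -1.0), 1.0))

    if abs(rho) >= 1.0 - 1e-14:
        if rho > 0:
            return ndtr(np.minimum(h, k))
        return np.clip(ndtr(h) + ndtr(k) - 1.0, 0.0, 1.0)

    # |h| below 1e-12 is replaced by 1e-12: the CDF is continuous with
    # bounded derivative, so the perturbation error is below 1e-12
    hs = np.clip(np.where(np.abs(h) < 1e-12, 1e-12, h), -_CLIP, _CLIP)
    ks = np.clip(np.where(np.abs(k) < 1e-12, 1e-12, k), -_CLIP, _CLIP)
    r = np.sqrt((1.0 - rho) * (1.0 + rho))
    with np.errstate(over="ignore"):
        a_h = np.clip((ks - rho * hs) / (hs * r), -1e15, 1e15)
        a_k = np.clip((hs - rho * ks) / (ks * r), -1e15, 1e15)
    res = 0.5 * (ndtr(hs) + ndtr(ks)) - owens_t(hs, a_h) - owens_t(ks, a_k)
    res = res - np.where(hs * ks < 0.0, 0.5, 0.0)
    return np.clip(res, 0.0, 1.0)


def bivariate_normal_orthant(lower_1, lower_2, rho: float):
    """P(Z1 > lower_1, Z2 > lower_2) for standard bivariate normal.

    Infinite lower bounds marginalize the corresponding dimension.
    """
    l1 = np.asarray(lower_1, dtype=float)
    l2 = np.asarray(lower_2, dtype=float)
    if np.isnan(l1).any() or np.isnan(l2).any():
        raise ValueError("NaN bounds in orthant probability")
    return bvn_cdf(-l1, -l2, rho)
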