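"""Shared statistical primitives: BH step-up FDR and the scaled-F
moment-matching used to moderate per-gene variances.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Ties receive the common adjusted value; the output preserves the
    ordering of the input p-values and satisfies ``p_adj >= p``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    n = p.size
    if n == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # step-up: running minimum from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-8) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by Newton iteration.

    Used to invert the log-variance spread into prior degrees of
    freedom.  Monotone decreasing, so the iteration from the asymptotic
    start ``x = 0.5 + 1/y`` converges quickly.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if -dif / x < tol:
            break
    return float(x)


def fit_scaled_f_prior(s2, df) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed sample variances.

    Under the hierarchical model ``s2 ~ s0^2 * F(df, d0)`` the log sample
    variance has known mean/variance in terms of di/tri-gamma functions;
    matching those moments yields closed-form estimates of the prior
    degrees of freedom ``d0`` and prior variance ``s0^2``.

    Parameters
    ----------
    s2 : array of per-gene sample variances (positive entries used).
    df : scalar or array of residual degrees of freedom.

    Returns
    -------
    (d0, s0_squared); ``d0`` may be ``inf`` when the variances are no
    more dispersed than chi-square sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def squeeze_variances(s2, df, d0: float, s0_sq: float) -> np.ndarray:
    """Posterior (shrunken) variances ``(d0*s0^2 + df*s2) / (d0 + df)``."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)
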