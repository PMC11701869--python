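"""Storey q-values.

q_i = pi0 * min_{p_(j) >= p_(i)} m p_(j) / j, with the null proportion pi0
estimated from the flat right tail of the p-value histogram: pi0(lambda) =
#{p > lambda} / (m (1 - lambda)) is computed on lambda = 0.05, ..., 0.95,
smoothed by a least-squares cubic, and read off at lambda = 0.95 (clamped
to (0, 1]).  Forcing pi0 = 1 recovers Benjamini-Hochberg exactly; for
short p-vectors (< 100) where the smoother is unstable, pi0 = 1 is used.
"""

from __future__ import annotations

import numpy as np


def estimate_pi0(p: np.ndarray) -> float:
    """Smoother-based estimate of the proportion of true nulls."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coef, 0.95))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """q-values for a vector of p-values.

    Parameters
    ----------
    p
        p-values in [0, 1].
    pi0
        Override the estimated null proportion (pi0 = 1 gives BH).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if pi0 is None:
        pi0 = 1.0 if m < 100 else estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # step-up: running minimum from the largest p down
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
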