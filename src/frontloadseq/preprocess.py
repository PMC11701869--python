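"""Count filtering, normalization, dispersion trend and the VST.

The chain mirrors standard bulk count-matrix quality control: drop
undetected genes, apply the pOverA low-expression filter (keep a gene if at
least a proportion P of samples show >= A counts), compute median-of-ratios
size factors, fit a parametric dispersion trend alpha(mu) = a0 + a1/mu by
robust least squares on per-gene method-of-moments dispersions, and apply a
variance-stabilizing transformation derived from that trend.

The VST is computed as the calibrated integral of 1/sqrt(var(mu)): for NB
counts var(mu) = mu + alpha(mu) * mu^2, and

    g(x) = int_0^x du / sqrt(u + alpha(u) u^2)

evaluated numerically on a log-spaced grid and scaled so that differences
of g approach log2 ratios for large counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, interpolate

from .simulate import dispersion_at


def detect_filter(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero counts in every sample; keep row order."""
    keep = counts.to_numpy().sum(axis=1) > 0
    return counts.loc[keep]


def pover_a_filter(counts: pd.DataFrame, p: float = 0.25, a: float = 10) -> pd.DataFrame:
    """Keep genes with at least ``a`` counts in at least ``p`` of samples.

    The threshold is inclusive on both sides (count >= a, proportion >= p),
    so a gene hit in exactly P of the samples is retained.  Idempotent.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if a < 0:
        raise ValueError(f"a must be >= 0, got {a}")
    values = counts.to_numpy()
    frac = (values >= a).mean(axis=1)
    return counts.loc[frac >= p]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The per-gene reference is the geometric mean across samples over genes
    expressed everywhere; each sample's factor is the median ratio of its
    counts to that reference.
    """
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter the matrix first"
        )
    logs = np.log(values[all_positive])
    log_ref = logs.mean(axis=1)
    log_s = np.median(logs - log_ref[:, None], axis=0)
    log_s = log_s - log_s.mean()  # geometric mean 1
    return pd.Series(np.exp(log_s), index=counts.columns, name="size_factor")


class DispersionTrend:
    """Parametric NB dispersion trend alpha(mu) = alpha_asym + alpha_extra/mu."""

    def __init__(
        self,
        alpha_asym: float,
        alpha_extra: float,
        gene_dispersions: pd.Series | None = None,
        gene_means: pd.Series | None = None,
    ) -> None:
        if alpha_asym <= 0 or alpha_extra < 0:
            raise ValueError("trend coefficients must be positive")
        self.alpha_asym = float(alpha_asym)
        self.alpha_extra = float(alpha_extra)
        self.gene_dispersions = gene_dispersions
        self.gene_means = gene_means

    def __call__(self, mu) -> np.ndarray:
        return dispersion_at(mu, (self.alpha_asym, self.alpha_extra))

    def trended(self, gene_means: pd.Series | None = None) -> pd.Series:
        means = gene_means if gene_means is not None else self.gene_means
        if means is None:
            raise ValueError("no gene means available")
        return pd.Series(self(means.to_numpy()), index=means.index, name="dispersion")

    def __repr__(self) -> str:  # noqa: D105
        return (
            f"DispersionTrend(alpha_asym={self.alpha_asym:.4g}, "
            f"alpha_extra={self.alpha_extra:.4g})"
        )


def gene_dispersions_mom(counts: pd.DataFrame, sf: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Method-of-moments dispersion per gene on normalized counts.

    alpha_g = max(0, (var - mu) / mu^2); genes whose normalized variance is
    at or below their mean get 0 (Poisson or underdispersed).
    """
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mu > 0, np.maximum(0.0, (var - mu) / mu**2), 0.0)
    return (
        pd.Series(alpha, index=counts.index, name="dispersion_mom"),
        pd.Series(mu, index=counts.index, name="base_mean"),
    )


def estimate_dispersion_trend(
    counts: pd.DataFrame,
    sf: pd.Series,
    tol: float = 1e-6,
    max_iter: int = 50,
    min_positive: int = 50,
) -> DispersionTrend:
    """Fit alpha(mu) = a0 + a1/mu by robust iteratively trimmed least squares.

    Genes with zero method-of-moments dispersion are excluded; each round
    refits ordinary least squares of alpha on 1/mu and drops points whose
    absolute residual exceeds 3 MAD, until the coefficients move by less
    than ``tol`` or ``max_iter`` rounds elapse.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate dispersions")
    alpha_g, mu_g = gene_dispersions_mom(counts, sf)
    mask = (alpha_g > 0) & (mu_g > 0)
    if mask.sum() < min_positive:
        raise ValueError(
            f"only {int(mask.sum())} genes with positive dispersion; "
            f"trend unreliable (need {min_positive})"
        )
    y = alpha_g[mask].to_numpy()
    x = 1.0 / mu_g[mask].to_numpy()
    keep = np.ones(len(y), dtype=bool)
    coef = np.array([np.median(y), 0.0])
    for _ in range(max_iter):
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        new_coef, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        resid = y - (new_coef[0] + new_coef[1] * x)
        mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
        scale = max(mad, 1e-12)
        new_keep = np.abs(resid - np.median(resid[keep])) <= 3.0 * scale
        converged = np.max(np.abs(new_coef - coef)) < tol
        coef = new_coef
        if converged and (new_keep == keep).all():
            break
        keep = new_keep
    alpha_asym = max(coef[0], 1e-8)
    alpha_extra = max(coef[1], 0.0)
    return DispersionTrend(alpha_asym, alpha_extra, alpha_g, mu_g)


class VstTransform:
    """Monotone variance-stabilizing map built from a dispersion trend.

    ``g`` integrates 1/sqrt(mu + alpha(mu) mu^2) on a log-spaced grid and is
    affinely calibrated so g(x2) - g(x1) -> log2(x2/x1) for large x, pinning
    g at the upper anchor to log2(anchor).
    """

    def __init__(self, trend: DispersionTrend, x_max: float = 1e7, n_grid: int = 2000):
        if not np.isfinite([trend.alpha_asym, trend.alpha_extra]).all():
            raise ValueError("non-finite dispersion trend")
        a0, a1 = trend.alpha_asym, trend.alpha_extra
        grid = np.concatenate([[0.0], np.logspace(-8, np.log10(x_max), n_grid)])
        u = grid
        var = u * (1.0 + a1) + a0 * u**2  # mu + (a0 + a1/mu) mu^2
        integrand = np.zeros_like(u)
        integrand[1:] = 1.0 / np.sqrt(var[1:])
        # 1/sqrt(u(1+a1)) is integrable at 0: use exact small-x antiderivative
        g = integrate.cumulative_trapezoid(integrand, u, initial=0.0)
        g += 0.0  # g(0) = 0 by construction
        # correct the [0, grid[1]] panel where the trapezoid rule is poor
        g0 = 2.0 * np.sqrt(grid[1] / (1.0 + a1))
        g[1:] += g0 - (g[1] - g[0])
        scale = np.sqrt(a0) / np.log(2.0)
        g_cal = g * scale
        anchor = grid[-1]
        g_cal += np.log2(anchor) - g_cal[-1]
        self._interp = interpolate.PchipInterpolator(grid, g_cal, extrapolate=False)
        self._x_max = x_max
        self._slope_hi = (g_cal[-1] - g_cal[-2]) / (grid[-1] - grid[-2])
        self.trend = trend

    def g(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.empty(x.shape)
        inside = x <= self._x_max
        out[inside] = self._interp(np.clip(x[inside], 0.0, None))
        if (~inside).any():
            out[~inside] = self._interp(self._x_max) + np.log2(x[~inside] / self._x_max)
        return out

    def __call__(self, counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
        norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
        return pd.DataFrame(self.g(norm), index=counts.index, columns=counts.columns)


def vst_transform(
    counts: pd.DataFrame, sf: pd.Series, trend: DispersionTrend
) -> pd.DataFrame:
    """Apply the calibrated VST to size-factor-normalized counts."""
    return VstTransform(trend)(counts, sf)


def flag_outlier_samples(
    counts: pd.DataFrame,
    k: float = 5.0,
    p: float = 0.25,
    a: float = 10,
) -> list[str]:
    """Flag samples far from the bulk in VST expression PC space.

    Runs a provisional filter + VST pass, projects samples onto the first
    two principal components, and flags samples whose Euclidean distance
    from the centroid exceeds median + k * MAD of all distances.  After
    removing flagged samples the caller should re-run filtering and the
    VST, mirroring standard practice.
    """
    if counts.shape[1] < 4:
        raise ValueError("need at least 4 samples to estimate outlier spread")
    filtered = pover_a_filter(detect_filter(counts), p=p, a=a)
    sf = size_factors(filtered)
    trend = estimate_dispersion_trend(filtered, sf)
    vst = vst_transform(filtered, sf, trend)
    x = vst.to_numpy().T  # samples x genes
    x = x - x.mean(axis=0)
    # two leading PCs via SVD
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    scores = x @ vt[:2].T
    d = np.linalg.norm(scores - scores.mean(axis=0), axis=1)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if not np.isfinite(k):
        return []
    cut = med + k * max(mad, 1e-12)
    return [s for s, di in zip(counts.columns, d) if di > cut]
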