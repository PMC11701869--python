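"""Per-gene negative-binomial mixed models for a 2 x 2 design.

Each gene is modelled as NB(mu_j, alpha_g) with log link,

    log mu_j = log s_j + x_j' beta + u_genotype(j),   u_k ~ N(0, sigma_u^2)

where x_j encodes origin, treatment and their interaction in sum-to-zero
(+1/-1) contrasts, s_j are size factors, and alpha_g is a fixed per-gene
dispersion supplied by the caller (typically the trended estimate).  The
marginal likelihood integrates the colony random intercepts by a Laplace
approximation; because colonies partition the samples, the penalized inner
problem separates into independent scalar Newton solves per colony.

Type-III Wald chi-square tests fall out of the fixed-effect covariance
(one coefficient per term in a 2 x 2 layout), and model-estimated cell
means are exp(x_cell' beta) at random effect zero on the normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .qvalue import storey_qvalues

CELL_ORDER = ["flat_stable", "flat_variable", "slope_stable", "slope_variable"]
#: sum-to-zero design rows for the four cells: [1, origin, treatment, o*t]
#: with origin +1 = flat, treatment +1 = variable.
CELL_DESIGN = np.array(
    [
        [1.0, 1.0, -1.0, -1.0],  # flat, stable
        [1.0, 1.0, 1.0, 1.0],  # flat, variable
        [1.0, -1.0, -1.0, 1.0],  # slope, stable
        [1.0, -1.0, 1.0, -1.0],  # slope, variable
    ]
)
TERMS = ["origin", "treatment", "interaction"]


def design_matrix(meta: pd.DataFrame) -> np.ndarray:
    """Sum-to-zero coded n x 4 fixed-effect design from sample metadata."""
    o = np.where(meta["origin"].to_numpy() == "flat", 1.0, -1.0)
    t = np.where(meta["treatment"].to_numpy() == "variable", 1.0, -1.0)
    X = np.column_stack([np.ones(len(meta)), o, t, o * t])
    cells = {(1.0, -1.0), (1.0, 1.0), (-1.0, -1.0), (-1.0, 1.0)}
    present = set(zip(o, t))
    if present != cells:
        missing = sorted(cells - present)
        raise ValueError(f"design is singular: empty origin/treatment cell(s) {missing}")
    return X


@dataclass
class GlmmFit:
    """Result of one per-gene NB mixed-model fit."""

    gene: str
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_u: float
    loglik: float
    converged: bool
    dispersion: float

    @property
    def cell_means(self) -> pd.Series:
        return estimated_group_means(self)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: float) -> float:
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu) + 1e-300)
        )
    )


class _LaplaceObjective:
    """Negative Laplace-approximated marginal log-likelihood.

    Parameter vector is (beta[0..3], sigma_u).  The random-effect modes are
    warm-started across calls, so the inner Newton solves typically need
    only a couple of iterations.
    """

    def __init__(self, y, X, offset, geno_idx, n_geno, dispersion):
        self.y = np.asarray(y, dtype=float)
        self.X = X
        self.offset = offset
        self.geno = geno_idx
        self.n_geno = n_geno
        self.r = 1.0 / dispersion
        self.u = np.zeros(n_geno)
        self.inner_tol = 1e-8
        self.inner_max = 50

    def _inner_modes(self, eta_fixed: np.ndarray, sigma2: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-colony penalized modes and curvature sums H_k."""
        y, r, geno = self.y, self.r, self.geno
        u = self.u.copy()
        for _ in range(self.inner_max):
            eta = eta_fixed + u[geno]
            mu = np.exp(eta)
            score = y - mu * (y + r) / (mu + r)
            w = mu * r * (y + r) / (mu + r) ** 2
            g = np.bincount(geno, weights=score, minlength=self.n_geno) - u / sigma2
            h = np.bincount(geno, weights=w, minlength=self.n_geno) + 1.0 / sigma2
            step = g / h
            # dampen huge steps for stability far from the optimum
            step = np.clip(step, -2.0, 2.0)
            u = u + step
            if np.max(np.abs(step)) < self.inner_tol:
                break
        self.u = u
        eta = eta_fixed + u[geno]
        mu = np.exp(eta)
        w = mu * r * (y + r) / (mu + r) ** 2
        H = np.bincount(geno, weights=w, minlength=self.n_geno)
        return u, H

    def __call__(self, params: np.ndarray) -> float:
        beta = params[:4]
        sigma_u = params[4]
        eta_fixed = self.offset + self.X @ beta
        eta_fixed = np.clip(eta_fixed, -30.0, 30.0)
        if sigma_u < 1e-6:
            mu = np.exp(eta_fixed)
            return -_nb_loglik(self.y, mu, self.r)
        sigma2 = sigma_u**2
        u, H = self._inner_modes(eta_fixed, sigma2)
        mu = np.exp(np.clip(eta_fixed + u[self.geno], -30.0, 30.0))
        ll = (
            _nb_loglik(self.y, mu, self.r)
            - np.sum(u**2) / (2.0 * sigma2)
            - 0.5 * np.sum(np.log1p(sigma2 * H))
        )
        return -ll


def _start_values(y, X, offset, meta) -> np.ndarray:
    """Cell-mean based starting beta and a modest sigma_u."""
    norm = y / np.exp(offset)
    logm = np.empty(4)
    o = X[:, 1]
    t = X[:, 2]
    for i, (oo, tt) in enumerate([(1, -1), (1, 1), (-1, -1), (-1, 1)]):
        sel = (o == oo) & (t == tt)
        logm[i] = np.log(max(norm[sel].mean(), 1e-3))
    beta0 = np.linalg.solve(CELL_DESIGN, logm)
    return np.concatenate([beta0, [0.1]])


def fit_gene_glmm(
    y: np.ndarray,
    meta: pd.DataFrame,
    dispersion: float,
    size_factors: pd.Series,
    gene: str = "",
    max_fun: int = 200,
) -> GlmmFit:
    """Fit the NB mixed model for one gene.

    Outer quasi-Newton (L-BFGS-B) over (beta, sigma_u) with sigma_u bounded
    below by zero; inner Newton solves per colony (tol 1e-8).  The Wald
    covariance is the inverse observed information of the Laplace objective,
    including the sigma_u row when the variance is away from the boundary.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    y = np.asarray(y, dtype=float)
    X = design_matrix(meta)
    sf = size_factors.loc[meta.index].to_numpy()
    offset = np.log(sf)
    geno_codes, geno_levels = pd.factorize(meta["genotype"], sort=True)
    obj = _LaplaceObjective(y, X, offset, geno_codes, len(geno_levels), dispersion)
    x0 = _start_values(y, X, offset, meta)
    res = optimize.minimize(
        obj,
        x0,
        method="L-BFGS-B",
        bounds=[(None, None)] * 4 + [(0.0, 10.0)],
        options={"maxfun": max_fun, "ftol": 1e-10, "gtol": 1e-6},
    )
    params = res.x
    beta = params[:4]
    sigma_u = params[4]
    converged = bool(res.success) and np.all(np.isfinite(params))

    cov_beta = np.full((4, 4), np.nan)
    if converged:
        include_sigma = sigma_u > 1e-4
        k = 5 if include_sigma else 4
        hess = _numeric_hessian(obj, params, k)
        try:
            cov = np.linalg.inv(hess)
            cov_beta = cov[:4, :4]
            if not np.all(np.isfinite(cov_beta)) or np.any(np.diag(cov_beta) <= 0):
                converged = False
        except np.linalg.LinAlgError:
            converged = False

    return GlmmFit(
        gene=gene,
        beta=beta,
        cov_beta=cov_beta,
        sigma2_u=float(sigma_u**2),
        loglik=-float(res.fun),
        converged=converged,
        dispersion=dispersion,
    )


def _numeric_hessian(obj, params: np.ndarray, k: int) -> np.ndarray:
    """Central-difference Hessian of ``obj`` in the first ``k`` parameters."""
    h = 1e-4 * np.maximum(1.0, np.abs(params[:k]))
    hess = np.empty((k, k))
    f0 = obj(params)
    for i in range(k):
        for j in range(i, k):
            pp = params.copy()
            if i == j:
                pp[i] = params[i] + h[i]
                fp = obj(pp)
                pp[i] = params[i] - h[i]
                fm = obj(pp)
                hess[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                vals = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    pp = params.copy()
                    pp[i] = params[i] + si * h[i]
                    pp[j] = params[j] + sj * h[j]
                    vals.append(obj(pp))
                hess[i, j] = hess[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * h[i] * h[j]
                )
    return hess


def wald_type3_tests(fit: GlmmFit) -> dict[str, tuple[float, float]]:
    """Per-term Wald chi-square and p (1 df each in the 2 x 2 design)."""
    out: dict[str, tuple[float, float]] = {}
    for i, term in enumerate(TERMS, start=1):
        if not fit.converged:
            out[term] = (np.nan, np.nan)
            continue
        w = fit.beta[i] ** 2 / fit.cov_beta[i, i]
        out[term] = (float(w), float(stats.chi2.sf(w, df=1)))
    return out


def estimated_group_means(fit: GlmmFit) -> pd.Series:
    """Model-estimated cell means at random effect 0, normalized scale."""
    if not fit.converged:
        return pd.Series(np.nan, index=CELL_ORDER)
    return pd.Series(np.exp(CELL_DESIGN @ fit.beta), index=CELL_ORDER)


def fit_all_genes(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    dispersions: pd.Series,
    size_factors: pd.Series,
) -> pd.DataFrame:
    """Fit every gene and assemble the DE table with per-term q-values.

    Genes whose fit does not converge keep a row with ``converged = False``
    and missing statistics; they are excluded from q-value estimation and
    from downstream frontloading, mirroring how a non-converging gene is
    dropped from the analysis set.
    """
    rows = []
    for gene in counts.index:
        fit = fit_gene_glmm(
            counts.loc[gene].to_numpy(),
            meta,
            float(dispersions.loc[gene]),
            size_factors,
            gene=gene,
        )
        tests = wald_type3_tests(fit)
        means = estimated_group_means(fit)
        row = {
            "gene": gene,
            "beta_intercept": fit.beta[0],
            "beta_origin": fit.beta[1],
            "beta_treatment": fit.beta[2],
            "beta_interaction": fit.beta[3],
            "sigma2_u": fit.sigma2_u,
            "dispersion": fit.dispersion,
            "converged": fit.converged,
        }
        for term in TERMS:
            row[f"chi2_{term}"], row[f"p_{term}"] = tests[term]
        for cell in CELL_ORDER:
            row[f"mean_{cell}"] = means[cell]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    ok = table["converged"] & table[[f"p_{t}" for t in TERMS]].notna().all(axis=1)
    for term in TERMS:
        q = np.full(len(table), np.nan)
        if ok.any():
            q[ok.to_numpy()] = storey_qvalues(table.loc[ok, f"p_{term}"].to_numpy())
        table[f"q_{term}"] = q
    return table
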