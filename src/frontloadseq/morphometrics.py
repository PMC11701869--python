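"""Linear mixed models for skeletal micromorphometry.

One random-intercept LMM per feature: value ~ origin * treatment with a
colony random effect (colonies nested within origin), fit by REML.  Fixed
effects use sum-to-zero contrasts so the type-III Wald chi-square tests
are marginal; estimated marginal means (EMMs) are model predictions per
origin x treatment cell at random effect zero, and all six pairwise cell
contrasts are adjusted with the studentized-range (Tukey HSD) correction
studentized on the residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .de_glmm import CELL_DESIGN, CELL_ORDER, TERMS


@dataclass
class LmmFit:
    """REML fit of one micromorphometric feature."""

    feature: str
    beta: np.ndarray  # intercept, origin, treatment, interaction
    cov_beta: np.ndarray
    colony_var: float
    residual_var: float
    converged: bool
    df_resid: float = np.inf


def _design(records: pd.DataFrame) -> np.ndarray:
    o = np.where(records["origin"].to_numpy() == "flat", 1.0, -1.0)
    t = np.where(records["treatment"].to_numpy() == "variable", 1.0, -1.0)
    return np.column_stack([np.ones(len(records)), o, t, o * t])


def fit_lmm_reml(records: pd.DataFrame, feature: str | None = None) -> LmmFit:
    """Fit the colony random-intercept LMM for one feature by REML."""
    if feature is not None:
        records = records[records["feature"] == feature]
    elif records["feature"].nunique() == 1:
        feature = records["feature"].iloc[0]
    else:
        raise ValueError("records contain multiple features; pass feature=")
    records = records.reset_index(drop=True)
    for origin in ("flat", "slope"):
        n_col = records.loc[records["origin"] == origin, "colony"].nunique()
        if n_col < 2:
            raise ValueError(f"need >= 2 colonies per origin (origin {origin!r} has {n_col})")
    cells = records.groupby(["origin", "treatment", "colony"]).size()
    if (cells == 1).all() and records.groupby("colony")[["origin", "treatment"]].nunique().max().max() == 1:
        raise ValueError(
            "colony is confounded with origin x treatment cells: one observation "
            "per cell and colony never crosses treatments"
        )
    X = _design(records)
    y = records["value"].to_numpy(dtype=float)
    groups = records["colony"].to_numpy()
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if res is None:
        raise np.linalg.LinAlgError(
            f"REML fit failed for feature {feature!r} with every optimizer"
        )
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:4, :4]
    colony_var = float(np.asarray(res.cov_re).ravel()[0])
    return LmmFit(
        feature=feature or "",
        beta=beta,
        cov_beta=cov,
        colony_var=colony_var,
        residual_var=float(res.scale),
        converged=bool(res.converged),
        df_resid=float(max(len(records) - X.shape[1], 1)),
    )


def wald_type3_anova(fit: LmmFit) -> pd.DataFrame:
    """Type-III Wald chi-square per term (1 df each in the 2 x 2 design)."""
    rows = []
    for i, term in enumerate(TERMS, start=1):
        var = max(float(fit.cov_beta[i, i]), 1e-300)
        chi2 = 0.0 if abs(fit.beta[i]) < 1e-12 else fit.beta[i] ** 2 / var
        rows.append(
            {
                "feature": fit.feature,
                "term": term,
                "chi2": float(chi2),
                "p": float(stats.chi2.sf(chi2, df=1)),
            }
        )
    return pd.DataFrame(rows)


def estimated_marginal_means(fit: LmmFit) -> pd.DataFrame:
    """EMMs per origin x treatment cell with standard errors."""
    means = CELL_DESIGN @ fit.beta
    var = np.einsum("ij,jk,ik->i", CELL_DESIGN, fit.cov_beta, CELL_DESIGN)
    var = np.clip(var, 0.0, None)
    return pd.DataFrame(
        {"feature": fit.feature, "cell": CELL_ORDER, "emmean": means, "se": np.sqrt(var)}
    ).set_index("cell")


def tukey_pairwise(fit: LmmFit) -> pd.DataFrame:
    """All six pairwise cell contrasts with Tukey-HSD-adjusted p-values.

    The adjustment uses the studentized range distribution for a family of
    four means, studentized on the residual degrees of freedom:
    q = |diff| / (SE / sqrt 2).
    """
    emm = estimated_marginal_means(fit)
    k = len(CELL_ORDER)
    df = min(fit.df_resid, 1e6)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(CELL_ORDER), 2):
        contrast = CELL_DESIGN[i] - CELL_DESIGN[j]
        diff = float(contrast @ fit.beta)
        se = float(np.sqrt(contrast @ fit.cov_beta @ contrast))
        z = diff / se if se > 0 else 0.0
        p_raw = float(2.0 * stats.t.sf(abs(z), df))
        q = abs(z) * np.sqrt(2.0)
        p_adj = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
        rows.append(
            {
                "feature": fit.feature,
                "contrast": f"{a} - {b}",
                "estimate": diff,
                "se": se,
                "z": z,
                "p_raw": p_raw,
                "p_tukey": max(p_adj, p_raw),
            }
        )
    return pd.DataFrame(rows)


def percent_change(reference: float, new: float) -> float:
    """Signed percent change from ``reference`` to ``new``."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (new - reference) / reference


def analyse_features(morpho: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ANOVA, EMM and Tukey tables across all features in a morpho table."""
    anovas, emms, contrasts = [], [], []
    for feature in morpho["feature"].unique():
        fit = fit_lmm_reml(morpho, feature)
        anovas.append(wald_type3_anova(fit))
        emms.append(estimated_marginal_means(fit).reset_index())
        contrasts.append(tukey_pairwise(fit))
    return (
        pd.concat(anovas, ignore_index=True),
        pd.concat(emms, ignore_index=True),
        pd.concat(contrasts, ignore_index=True),
    )
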