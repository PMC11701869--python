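"""End-to-end validation benchmarks.

Each function recomputes one headline quantity of the pipeline from
scratch on synthetic data with planted truth (or on the study's printed
inputs, for the worked-example arithmetic) and returns it together with
the problem size used.  The acceptance script and the acceptance tests
both drive these functions; nothing here reads stored results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .coexpression import GREY, cut_modules, signed_adjacency, tom_similarity
from .de_glmm import fit_all_genes, fit_gene_glmm, wald_type3_tests
from .enrichment import wallenius_test
from .frontloading import classify_table, frontload_summary
from .morphometrics import (
    estimated_marginal_means,
    fit_lmm_reml,
    percent_change,
    tukey_pairwise,
)
from .preprocess import DispersionTrend, estimate_dispersion_trend, size_factors, vst_transform
from .qvalue import storey_qvalues
from .simulate import (
    SimDesign,
    diel_amplitude_summary,
    dispersion_at,
    simulate_counts,
    simulate_frontload_validation,
    simulate_morphometrics,
    simulate_pco2_series,
)

#: printed study inputs for the worked-example arithmetic
DIEL_AMPLITUDES_UATM = {"variable": 911.3, "stable": 218.3}
SPINE_LENGTH_UM = {"reference": 109.0, "new": 98.0}
RAD_AREA_UM = {"reference": 13.0, "new": 21.0}
RADS_PER_SPINE = {"reference": 21.0, "new": 30.0}
MAPPING_RATE_PCT = {"reference": 29.10, "new": 72.48}


def worked_examples() -> dict[str, float]:
    """Deterministic arithmetic on the study's printed measurements.

    The diel-amplitude fold difference is recomputed by generating the two
    treatment pCO2 sinusoids at their recorded mean diel amplitudes and
    summarizing the mean daily range of each series.
    """
    variable = simulate_pco2_series(800.0, DIEL_AMPLITUDES_UATM["variable"], days=14)
    stable = simulate_pco2_series(450.0, DIEL_AMPLITUDES_UATM["stable"], days=14)
    fold = diel_amplitude_summary(variable) / diel_amplitude_summary(stable)
    return {
        "diel_amplitude_fold": round(fold, 1),
        "spine_length_pct_change": percent_change(**SPINE_LENGTH_UM),
        "rad_area_pct_change": percent_change(**RAD_AREA_UM),
        "rad_count_pct_change": percent_change(**RADS_PER_SPINE),
        "mapping_rate_pct_change": percent_change(**MAPPING_RATE_PCT),
    }


def frontload_recovery(seed: int = 0) -> dict[str, float]:
    """Sensitivity/specificity of the frontloading classifier.

    200 genes, 10% planted frontloaded at 2-fold effects, colony SD 0.3,
    46-sample analysis set; the full pipeline (size factors, trended
    dispersions, NB-GLMM estimated means) feeds the classifier.
    """
    counts, meta, truth = simulate_frontload_validation(
        n_genes=200, frontload_prop=0.1, effect=2.0, genotype_sd=0.3, seed=seed
    )
    meta = meta[meta["genotype"] != "F12"]  # 11/11/12/12 analysis set
    counts = counts[meta.index]
    sf = size_factors(counts)
    trend = estimate_dispersion_trend(counts, sf)
    table = fit_all_genes(counts, meta, trend.trended(), sf)
    records = classify_table(table)
    pred = records["frontloaded"]
    true = (truth.genes["class_label"] == "frontloaded").reindex(pred.index)
    n_front, prop = frontload_summary(records)
    return {
        "sensitivity": float((pred & true).sum() / true.sum()),
        "specificity": float((~pred & ~true).sum() / (~true).sum()),
        "proportion_called": prop,
        "n": len(records),
    }


def glmm_interaction_type1(seed: int = 0, n_genes: int = 2000) -> dict[str, float]:
    """Empirical size of the interaction Wald test on null genes.

    Counts are simulated with no origin/treatment effects, colony SD 0.3
    and the configured NB dispersion trend; each gene's fit receives its
    true generative dispersion so the check isolates the calibration of
    the Laplace/Wald machinery.
    """
    design = SimDesign(
        n_genes=n_genes, seed=seed, genotype_sd=0.3, class_proportions={"null": 1.0}
    )
    counts, meta, truth = simulate_counts(design)
    sf = truth.size_factors
    ps = []
    for gene in counts.index:
        alpha = float(
            dispersion_at(truth.genes.loc[gene, "m_slope_stable"], design.dispersion_trend)
        )
        fit = fit_gene_glmm(counts.loc[gene].to_numpy(), meta, alpha, sf, gene=gene)
        p = wald_type3_tests(fit)["interaction"][1]
        if np.isfinite(p):
            ps.append(p)
    ps = np.asarray(ps)
    return {"type1_error": float((ps < 0.05).mean()), "n": len(ps)}


def tom_oracle_error(seed: int = 0, n_matrices: int = 100, n_nodes: int = 10) -> dict:
    """Worst deviation of the TOM from a brute-force triple sum."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        a = rng.uniform(size=(n_nodes, n_nodes))
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        for i in range(n_nodes):
            for j in range(n_nodes):
                if i == j:
                    continue
                s = sum(a[i, u] * a[u, j] for u in range(n_nodes) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n_nodes) if u != i)
                kj = sum(a[j, u] for u in range(n_nodes) if u != j)
                ref = (s + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
                worst = max(worst, abs(tom[i, j] - ref))
    return {"max_abs_error": worst, "n": n_matrices}


def module_recovery_ari(seed: int = 0) -> dict[str, float]:
    """Adjusted Rand index on 3 planted 60-gene blocks plus 50 noise genes."""
    rng = np.random.default_rng(seed)
    lam = np.sqrt(0.8 / 0.2)
    rows, labels_true = [], []
    for b in range(3):
        f = rng.normal(size=46)
        for _ in range(60):
            rows.append(lam * f + rng.normal(size=46))
            labels_true.append(b)
    for _ in range(50):
        rows.append(rng.normal(size=46))
        labels_true.append(-1)
    expr = pd.DataFrame(rows, index=[f"g{i:04d}" for i in range(len(rows))])
    tom = tom_similarity(signed_adjacency(expr, beta=5))
    labels = cut_modules(1.0 - tom, min_module_size=30, deep_split=1)
    ari = adjusted_rand_score(labels_true, pd.factorize(labels)[0])
    return {
        "ari": float(ari),
        "n_modules": int(labels[labels != GREY].nunique()),
        "n": len(expr),
    }


def wallenius_reduction() -> dict[str, float]:
    """Central-hypergeometric reduction of the Wallenius test at odds 1."""
    worst = 0.0
    for N, K, n, x in [(20, 5, 10, 4), (30, 6, 12, 3), (50, 10, 25, 8), (15, 4, 5, 2)]:
        genes = [f"g{i}" for i in range(N)]
        flags = pd.Series([1.0] * n + [0.0] * (N - n), index=genes)
        term = genes[:x] + genes[n : n + (K - x)]
        p = wallenius_test(term, flags, odds=1.0)
        worst = max(worst, abs(p - stats.hypergeom.sf(x - 1, N, K, n)))
    genes = [f"g{i}" for i in range(20)]
    flags = pd.Series([1.0] * 10 + [0.0] * 10, index=genes)
    example_p = wallenius_test(["g0", "g1", "g2", "g3", "g10"], flags, odds=1.0)
    return {"max_abs_error": worst, "example_p": example_p, "n": 4}


def vst_flatness(seed: int = 0, n_genes: int = 3000) -> dict[str, float]:
    """Slope of per-gene SD against mean after the VST on NB counts with
    dispersion trend (0.1, 5)."""
    design = SimDesign(
        n_genes=n_genes, seed=seed, genotype_sd=0.0,
        class_proportions={"null": 1.0}, dispersion_trend=(0.1, 5.0),
    )
    counts, _, truth = simulate_counts(design)
    v = vst_transform(counts, truth.size_factors, DispersionTrend(0.1, 5.0))
    slope = float(np.polyfit(v.mean(axis=1), v.std(axis=1, ddof=1), 1)[0])
    return {"sd_vs_mean_slope": slope, "n": n_genes}


def emm_identity(seed: int = 0) -> dict[str, float]:
    """EMMs on balanced zero-noise data reproduce the cell means exactly."""
    cells = [("flat", "stable"), ("flat", "variable"), ("slope", "stable"), ("slope", "variable")]
    means = [0.12, 0.18, 0.17, 0.13]
    spec = {"f": {"cells": dict(zip(cells, means)), "colony_sd": 0.0, "residual_sd": 0.0}}
    df = simulate_morphometrics(spec, n_per_cell=4, seed=seed)
    emm = estimated_marginal_means(fit_lmm_reml(df, "f"))
    err = float(np.max(np.abs(emm["emmean"].to_numpy() - np.array(means))))
    return {"max_abs_error": err, "n": len(df)}


def tukey_fwer(seed: int = 0, runs: int = 2000) -> dict[str, float]:
    """Family-wise error of Tukey-adjusted contrasts on null features."""
    cells = [("flat", "stable"), ("flat", "variable"), ("slope", "stable"), ("slope", "variable")]
    spec = {"f": {"cells": {c: 10.0 for c in cells}, "colony_sd": 0.5, "residual_sd": 1.0}}
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=runs)
    hits = 0
    for s in sub_seeds:
        df = simulate_morphometrics(spec, n_per_cell=24, n_colonies_per_origin=6, seed=int(s))
        tk = tukey_pairwise(fit_lmm_reml(df, "f"))
        hits += int((tk["p_tukey"] < 0.05).any())
    return {"fwer": hits / runs, "n": runs}


def bh_qvalue_checks(seed: int = 0) -> dict[str, float]:
    """Hand-checkable multiple-testing identities."""
    q_hand = storey_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=2000)
    q = storey_qvalues(p)
    order = np.argsort(p)
    worst_violation = float(np.min(np.diff(q[order]), initial=0.0))
    return {
        "bh_hand_case_max": float(q_hand.max()),
        "bh_hand_case_min": float(q_hand.min()),
        "q_monotone_min_step": worst_violation,
        "n": len(p),
    }
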