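"""NB mixed-model differential expression: oracles and calibration."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from frontloadseq.de_glmm import (
    CELL_DESIGN,
    CELL_ORDER,
    GlmmFit,
    _LaplaceObjective,
    design_matrix,
    estimated_group_means,
    fit_all_genes,
    fit_gene_glmm,
    wald_type3_tests,
)
from frontloadseq.qvalue import estimate_pi0, storey_qvalues
from frontloadseq.simulate import SimDesign, make_sample_meta, simulate_counts


def _nb_counts(rng, meta, beta, sigma_u, alpha, sf=None):
    """Draw one gene's counts directly from the model."""
    X = design_matrix(meta)
    genotypes = meta["genotype"].unique()
    u = dict(zip(genotypes, rng.normal(0.0, sigma_u, size=len(genotypes))))
    eta = X @ beta + np.array([u[g] for g in meta["genotype"]])
    if sf is not None:
        eta = eta + np.log(sf.to_numpy())
    mu = np.exp(eta)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


@pytest.fixture(scope="module")
def unit_sf(meta48):
    return pd.Series(1.0, index=meta48.index)


class TestFitGeneGlmm:
    def test_reduces_to_fixed_effects_glm_when_no_colony_variance(self, meta48, unit_sf):
        """sigma_u = 0 data: variance estimate collapses and the fixed
        effects match a plain NB GLM within 2 SE."""
        rng = np.random.default_rng(0)
        X = design_matrix(meta48)
        beta_true = np.array([np.log(500.0), 0.1, 0.0, 0.0])
        for _ in range(8):
            y = _nb_counts(rng, meta48, beta_true, 0.0, 0.01)
            fit = fit_gene_glmm(y, meta48, 0.01, unit_sf)
            glm = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=0.01)
            ).fit()
            se = np.sqrt(np.diag(glm.cov_params()))
            assert fit.sigma2_u <= 0.01
            assert np.all(np.abs(fit.beta - glm.params) < 2 * se)

    def test_origin_effect_recovered_without_bias(self, meta48, unit_sf):
        """beta = (log 100, log 2, 0, 0), sigma_u = 0.3, 24 colonies:
        the origin coefficient is unbiased to < 0.05 over 500 genes."""
        rng = np.random.default_rng(1)
        beta_true = np.array([np.log(100.0), np.log(2.0), 0.0, 0.0])
        estimates = []
        for _ in range(500):
            y = _nb_counts(rng, meta48, beta_true, 0.3, 0.15)
            fit = fit_gene_glmm(y, meta48, 0.15, unit_sf)
            if fit.converged:
                estimates.append(fit.beta[1])
        assert len(estimates) > 480
        assert abs(np.mean(estimates) - np.log(2.0)) < 0.05

    def test_constant_counts_give_flat_fit(self, meta48, unit_sf):
        y = np.full(len(meta48), 64.0)
        fit = fit_gene_glmm(y, meta48, 0.1, unit_sf)
        assert fit.beta[0] == pytest.approx(np.log(64.0), abs=1e-3)
        assert np.allclose(fit.beta[1:], 0.0, atol=1e-3)

    def test_empty_cell_is_a_singular_design_error(self, meta48, unit_sf):
        sub = meta48[
            ~((meta48["origin"] == "flat") & (meta48["treatment"] == "variable"))
        ]
        with pytest.raises(ValueError, match="cell"):
            fit_gene_glmm(np.ones(len(sub)), sub, 0.1, unit_sf.loc[sub.index])

    def test_laplace_objective_not_worse_than_glm_solution(self, meta48, unit_sf):
        """The optimum dominates the (GLM beta, sigma_u = 0) point."""
        rng = np.random.default_rng(2)
        y = _nb_counts(rng, meta48, np.array([np.log(200.0), 0.2, 0.1, 0.0]), 0.3, 0.1)
        fit = fit_gene_glmm(y, meta48, 0.1, unit_sf)
        X = design_matrix(meta48)
        glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.1)).fit()
        geno_codes, levels = pd.factorize(meta48["genotype"], sort=True)
        obj = _LaplaceObjective(
            y, X, np.zeros(len(y)), geno_codes, len(levels), 0.1
        )
        at_glm = obj(np.concatenate([glm.params, [0.0]]))
        assert -fit.loglik <= at_glm + 1e-6

    def test_doubled_size_factors_shift_only_intercept(self, meta48, unit_sf):
        rng = np.random.default_rng(3)
        y = _nb_counts(rng, meta48, np.array([np.log(150.0), 0.3, 0.0, 0.0]), 0.2, 0.1)
        fit1 = fit_gene_glmm(y, meta48, 0.1, unit_sf)
        fit2 = fit_gene_glmm(y, meta48, 0.1, 2.0 * unit_sf)
        np.testing.assert_allclose(fit1.beta[1:], fit2.beta[1:], atol=5e-3)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0] - np.log(2.0), abs=5e-3)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_glmmtmb_reference_fit(self, meta48, unit_sf, tmp_path):
        """Independent cross-check of one Laplace fit against glmmTMB with
        the same fixed dispersion and contrasts."""
        rng = np.random.default_rng(4)
        beta_true = np.array([np.log(120.0), 0.3, -0.1, 0.05])
        y = _nb_counts(rng, meta48, beta_true, 0.4, 0.12)
        fit = fit_gene_glmm(y, meta48, 0.12, unit_sf)
        df = meta48.copy()
        df["y"] = y
        df.to_csv(tmp_path / "gene.csv", index=False)
        script = textwrap.dedent("""
            suppressMessages(library(glmmTMB))
            d <- read.csv(file.path("%s", "gene.csv"))
            d$o <- ifelse(d$origin == "flat", 1, -1)
            d$t <- ifelse(d$treatment == "variable", 1, -1)
            m <- glmmTMB(y ~ o * t + (1 | genotype), family = nbinom2, data = d,
                         start = list(betad = log(1 / 0.12)),
                         map = list(betad = factor(NA)))
            co <- summary(m)$coefficients$cond
            sdre <- attr(VarCorr(m)$cond$genotype, "stddev")
            cat(co[, 1], co[, 2], sdre, sep = "\\n")
        """ % tmp_path)
        (tmp_path / "fit.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "fit.R")],
            capture_output=True, text=True, timeout=300, check=True,
        )
        values = np.array([float(v) for v in out.stdout.split()])
        r_beta, r_se, r_sigma = values[:4], values[4:8], values[8]
        np.testing.assert_allclose(fit.beta, r_beta, atol=1e-3)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.cov_beta)), r_se, rtol=0.05
        )
        assert np.sqrt(fit.sigma2_u) == pytest.approx(r_sigma, abs=5e-3)


class TestWaldTests:
    def test_z_of_1point96_gives_chi2_3point84(self):
        fit = GlmmFit(
            gene="g",
            beta=np.array([1.0, 0.0, 0.0, 0.196]),
            cov_beta=np.diag([1.0, 1.0, 1.0, 0.01]),
            sigma2_u=0.0,
            loglik=0.0,
            converged=True,
            dispersion=0.1,
        )
        w, p = wald_type3_tests(fit)["interaction"]
        assert w == pytest.approx(3.8416, abs=1e-4)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_interaction_p_uniform_under_main_effects_only(self, meta48, unit_sf):
        rng = np.random.default_rng(5)
        beta_true = np.array([np.log(300.0), 0.5, 0.3, 0.0])
        ps = []
        for _ in range(300):
            y = _nb_counts(rng, meta48, beta_true, 0.3, 0.1)
            fit = fit_gene_glmm(y, meta48, 0.1, unit_sf)
            if fit.converged:
                ps.append(wald_type3_tests(fit)["interaction"][1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_nonconverged_fit_yields_missing_values(self):
        fit = GlmmFit("g", np.full(4, np.nan), np.full((4, 4), np.nan),
                      0.0, 0.0, False, 0.1)
        assert all(np.isnan(v) for pair in wald_type3_tests(fit).values() for v in pair)


class TestEstimatedMeans:
    def test_intercept_only_gives_equal_means(self):
        fit = GlmmFit("g", np.array([np.log(10.0), 0, 0, 0]), np.eye(4),
                      0.0, 0.0, True, 0.1)
        assert np.allclose(estimated_group_means(fit).to_numpy(), 10.0)

    def test_matches_direct_evaluation_of_cell_design(self):
        beta = np.array([np.log(10.0), np.log(2.0), 0.3, -0.1])
        fit = GlmmFit("g", beta, np.eye(4), 0.0, 0.0, True, 0.1)
        expected = np.exp(CELL_DESIGN @ beta)
        np.testing.assert_allclose(
            estimated_group_means(fit).to_numpy(), expected
        )
        # flat cells carry exp(beta0 + beta1 ...): 2-fold origin ratio
        m = estimated_group_means(fit)
        ratio = (m["flat_stable"] * m["flat_variable"]) / (
            m["slope_stable"] * m["slope_variable"]
        )
        assert ratio == pytest.approx(np.exp(4 * beta[1]))

    def test_invariant_to_genotype_relabelling(self, meta48, unit_sf):
        rng = np.random.default_rng(6)
        y = _nb_counts(rng, meta48, np.array([np.log(80.0), 0.2, 0.0, 0.0]), 0.3, 0.1)
        fit1 = fit_gene_glmm(y, meta48, 0.1, unit_sf)
        relabel = meta48.copy()
        relabel["genotype"] = "x_" + relabel["genotype"]
        fit2 = fit_gene_glmm(y, relabel, 0.1, unit_sf)
        np.testing.assert_allclose(
            estimated_group_means(fit1).to_numpy(),
            estimated_group_means(fit2).to_numpy(),
            rtol=1e-6,
        )


class TestStoreyQvalues:
    def test_bh_hand_case_with_pi0_forced_to_one(self):
        q = storey_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
        np.testing.assert_allclose(q, 0.04)

    def test_pi0_near_one_for_uniform_pvalues(self):
        rng = np.random.default_rng(7)
        assert 0.9 <= estimate_pi0(rng.uniform(size=5000)) <= 1.0

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=500)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.5, 1.5]))


class TestPower:
    def test_origin_de_detected_with_good_power(self, meta48):
        """2-fold origin effects at study scale reach > 0.8 power at
        q < 0.05 (500-gene simulation, half planted)."""
        design = SimDesign(
            n_genes=500, seed=9, genotype_sd=0.3,
            class_proportions={"null": 0.5, "origin_de": 0.5},
        )
        counts, meta, truth = simulate_counts(design)
        meta = meta[meta["genotype"] != "F12"]
        counts = counts[meta.index]
        from frontloadseq.preprocess import estimate_dispersion_trend, size_factors

        sf = size_factors(counts)
        trend = estimate_dispersion_trend(counts, sf)
        table = fit_all_genes(counts, meta, trend.trended(), sf)
        planted = truth.genes["class_label"] == "origin_de"
        hits = table.loc[planted.to_numpy(), "q_origin"] < 0.05
        assert hits.mean() > 0.8
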