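"""Synthetic data with planted ground truth.

Emulates the structure of a two-origin (reef flat vs. reef slope), two
pCO2-treatment (stable vs. variable) coral transplant experiment: negative
binomial tag-counts with colony (genotype) random intercepts, a planted
frontloaded gene class, planted correlated-gene modules tied to latent
factors, gene lengths with an optional length/DE bias, diel pCO2 series,
and skeletal micromorphometric measurements with colony random effects.

Every generator consumes a :class:`numpy.random.Generator` derived from the
design seed, so identical designs reproduce bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GoMap, ORIGINS, TREATMENTS

CELLS = [("flat", "stable"), ("flat", "variable"), ("slope", "stable"), ("slope", "variable")]
CELL_COLS = ["m_flat_stable", "m_flat_variable", "m_slope_stable", "m_slope_variable"]

GENE_CLASSES = ("null", "origin_de", "treatment_de", "interaction", "frontloaded")


@dataclass
class SimDesign:
    """Parameters of the simulated experiment.

    The defaults mirror the study layout: 12 colonies per origin with one
    fragment per colony per treatment (48 samples before any exclusions),
    colony random-intercept SD 0.3 on the natural-log scale, an NB
    dispersion trend alpha(mu) = alpha_asym + alpha_extra/mu, and 2-fold
    planted effects.
    """

    n_genes: int = 2000
    n_genotypes_per_origin: int = 12
    replicates_per_genotype_per_treatment: int = 1
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "null": 0.70,
            "origin_de": 0.10,
            "treatment_de": 0.05,
            "interaction": 0.05,
            "frontloaded": 0.10,
        }
    )
    baseline_log_mean_range: tuple[float, float] = (np.log(10.0), np.log(1000.0))
    dispersion_trend: tuple[float, float] = (0.1, 5.0)
    genotype_sd: float = 0.3
    frontload_effect: float = 2.0
    slope_response_effect: float = 2.0
    de_effect: float = 2.0
    module_spec: Sequence[tuple[int, float]] = ()
    length_bias_strength: float = 0.0
    n_go_categories: int = 50
    n_linked_go_categories: int = 2
    go_size_range: tuple[int, int] = (10, 200)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")
        for name in ("frontload_effect", "slope_response_effect", "de_effect"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        a, b = self.dispersion_trend
        if a <= 0 or b < 0:
            raise ValueError("dispersion trend parameters must be positive")
        if self.genotype_sd < 0:
            raise ValueError("genotype_sd must be >= 0")
        if self.length_bias_strength < 0:
            raise ValueError("length_bias_strength must be >= 0")


@dataclass
class SimTruth:
    """Planted truth emitted alongside the simulated counts."""

    genes: pd.DataFrame  # class_label, four true cell means, module
    genotype_effects: pd.DataFrame  # genes x genotypes, log scale
    latent_factors: pd.DataFrame  # modules x samples
    size_factors: pd.Series  # per-sample sequencing-depth multipliers

    def to_table(self) -> pd.DataFrame:
        return self.genes.copy()


def _class_counts(proportions: Mapping[str, float], n_genes: int) -> dict[str, int]:
    """Largest-remainder apportionment so counts are exact for round shares."""
    raw = {c: proportions.get(c, 0.0) * n_genes for c in GENE_CLASSES}
    counts = {c: int(np.floor(v + 1e-9)) for c, v in raw.items()}
    short = n_genes - sum(counts.values())
    if short:
        remainders = sorted(
            GENE_CLASSES, key=lambda c: (raw[c] - counts[c]), reverse=True
        )
        for c in remainders[:short]:
            counts[c] += 1
    return counts


def make_sample_meta(design: SimDesign) -> pd.DataFrame:
    rows = []
    for origin in ORIGINS:
        prefix = "F" if origin == "flat" else "S"
        for g in range(design.n_genotypes_per_origin):
            genotype = f"{prefix}{g + 1:02d}"
            for treatment in TREATMENTS:
                for r in range(design.replicates_per_genotype_per_treatment):
                    rows.append(
                        {
                            "sample_id": f"{genotype}_{treatment[:3]}_{r + 1}",
                            "origin": origin,
                            "treatment": treatment,
                            "genotype": genotype,
                        }
                    )
    meta = pd.DataFrame(rows)
    return meta.set_index("sample_id", drop=False)


def _cell_means(design: SimDesign, classes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """True per-gene means for the four origin x treatment cells.

    Frontloaded genes: elevated flat baseline held flat across treatments,
    with the slope origin upregulating under the variable treatment, so the
    true control ratio is frontload_effect (> 1) and the true fold-change
    ratio is 1/slope_response_effect (< 1) exactly.
    """
    n = len(classes)
    lo, hi = design.baseline_log_mean_range
    base = np.exp(rng.uniform(lo, hi, size=n))
    m = np.tile(base[:, None], (1, 4))  # fs, fv, ss, sv
    fold = design.de_effect
    signs = rng.choice([1.0, -1.0], size=n)
    for i, cls in enumerate(classes):
        if cls == "origin_de":
            f = fold ** signs[i]
            m[i, 0] *= f
            m[i, 1] *= f
        elif cls == "treatment_de":
            f = fold ** signs[i]
            m[i, 1] *= f
            m[i, 3] *= f
        elif cls == "interaction":
            # opposite treatment responses by origin, crossing interaction
            m[i, 1] *= fold
            m[i, 3] /= fold
        elif cls == "frontloaded":
            m[i, 0] *= design.frontload_effect
            m[i, 1] = m[i, 0]
            m[i, 3] *= design.slope_response_effect
    return m


def dispersion_at(mean: np.ndarray, trend: tuple[float, float]) -> np.ndarray:
    a, b = trend
    return a + b / np.maximum(np.asarray(mean, dtype=float), 1e-12)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + alpha * mu^2 (Poisson when alpha -> 0)."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        r = 1.0 / alpha[~poisson]
        p = r / (r + mu[~poisson])
        out[~poisson] = rng.negative_binomial(r, p)
    return out


def simulate_counts(design: SimDesign) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw the full count matrix plus metadata and planted truth."""
    rng = np.random.default_rng(design.seed)
    meta = make_sample_meta(design)
    n_samples = len(meta)
    n = design.n_genes

    counts_by_class = _class_counts(design.class_proportions, n)
    classes = np.concatenate(
        [np.repeat(cls, counts_by_class[cls]) for cls in GENE_CLASSES]
    )
    rng.shuffle(classes)
    gene_ids = np.array([f"gene{i + 1:05d}" for i in range(n)])

    m = _cell_means(design, classes, rng)

    # planted co-expression blocks live in the null class so module structure
    # is not confounded with the planted DE contrasts
    module_of = np.full(n, "", dtype=object)
    loadings = np.zeros(n)
    null_idx = np.flatnonzero(classes == "null")
    needed = sum(size for size, _ in design.module_spec)
    if needed > len(null_idx):
        raise ValueError(
            f"module_spec needs {needed} genes but only {len(null_idx)} null genes"
        )
    cursor = 0
    module_ids = []
    for k, (size, loading) in enumerate(design.module_spec):
        mod = f"M{k + 1}"
        module_ids.append(mod)
        members = null_idx[cursor : cursor + size]
        cursor += size
        module_of[members] = mod
        loadings[members] = loading

    factors = pd.DataFrame(
        rng.normal(size=(len(module_ids), n_samples)),
        index=module_ids,
        columns=meta.index,
    )

    genotypes = meta["genotype"].unique()
    u = rng.normal(0.0, design.genotype_sd, size=(n, len(genotypes)))
    genotype_effects = pd.DataFrame(u, index=gene_ids, columns=genotypes)
    geno_col = {g: j for j, g in enumerate(genotypes)}
    sample_geno = np.array([geno_col[g] for g in meta["genotype"]])

    lo, hi = design.size_factor_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    size_factors = pd.Series(s, index=meta.index, name="size_factor")

    cell_index = {cell: i for i, cell in enumerate(CELLS)}
    sample_cell = np.array(
        [cell_index[(o, t)] for o, t in zip(meta["origin"], meta["treatment"])]
    )

    mu = m[:, sample_cell] * np.exp(u[:, sample_geno]) * s[None, :]
    if len(module_ids):
        fac = np.zeros((n, n_samples))
        fmat = factors.to_numpy()
        for mod_idx, mod in enumerate(module_ids):
            members = np.flatnonzero(module_of == mod)
            fac[members, :] = loadings[members, None] * fmat[mod_idx][None, :]
        mu = mu * np.exp(fac)
    alpha = dispersion_at(m[:, sample_cell], design.dispersion_trend)
    values = _nb_draw(rng, mu, alpha)

    counts = pd.DataFrame(values, index=gene_ids, columns=meta.index)
    counts.index.name = "gene"

    genes = pd.DataFrame(
        {
            "class_label": classes,
            "m_flat_stable": m[:, 0],
            "m_flat_variable": m[:, 1],
            "m_slope_stable": m[:, 2],
            "m_slope_variable": m[:, 3],
            "module": module_of,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    truth = SimTruth(
        genes=genes,
        genotype_effects=genotype_effects,
        latent_factors=factors,
        size_factors=size_factors,
    )
    return counts, meta, truth


def simulate_frontload_validation(
    n_genes: int = 200,
    frontload_prop: float = 0.1,
    effect: float = 2.0,
    genotype_sd: float = 0.3,
    seed: int = 0,
    design: SimDesign | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Counts for validating the frontloading classifier.

    Genes are planted in the four quadrants of (control ratio C,
    fold-change ratio F) space at ``effect``-fold distances from both
    decision boundaries: a ``frontload_prop`` share in the frontloaded
    quadrant (C = effect, F = 1/effect) and the rest spread evenly over
    the other three.  No gene sits on a boundary, so the planted labels
    are decidable from true means and recoverable from estimates.  The
    slope/flat treatment responses are split geometrically
    (rho_slope = F^-1/2, rho_flat = F^1/2) around the shared baseline.
    """
    base_design = design or SimDesign(
        n_genes=n_genes, genotype_sd=genotype_sd, seed=seed
    )
    rng = np.random.default_rng(seed)
    meta = make_sample_meta(base_design)
    quadrants = {
        "frontloaded": (effect, 1.0 / effect),
        "high_flat_responsive": (effect, effect),
        "low_flat_dampened": (1.0 / effect, 1.0 / effect),
        "low_flat_responsive": (1.0 / effect, effect),
    }
    n_front = int(round(frontload_prop * n_genes))
    others = [q for q in quadrants if q != "frontloaded"]
    labels = ["frontloaded"] * n_front + [
        others[i % 3] for i in range(n_genes - n_front)
    ]
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)

    lo, hi = base_design.baseline_log_mean_range
    base = np.exp(rng.uniform(lo, hi, size=n_genes))
    m = np.empty((n_genes, 4))
    for i, lab in enumerate(labels):
        C, F = quadrants[lab]
        rho_s, rho_f = F**-0.5, F**0.5
        m[i] = [C * base[i], C * base[i] * rho_f, base[i], base[i] * rho_s]

    gene_ids = np.array([f"gene{i + 1:05d}" for i in range(n_genes)])
    genotypes = meta["genotype"].unique()
    u = rng.normal(0.0, genotype_sd, size=(n_genes, len(genotypes)))
    geno_col = {g: j for j, g in enumerate(genotypes)}
    sample_geno = np.array([geno_col[g] for g in meta["genotype"]])
    cell_index = {cell: i for i, cell in enumerate(CELLS)}
    sample_cell = np.array(
        [cell_index[(o, t)] for o, t in zip(meta["origin"], meta["treatment"])]
    )
    lo_s, hi_s = base_design.size_factor_range
    s = np.exp(rng.uniform(np.log(lo_s), np.log(hi_s), size=len(meta)))
    mu = m[:, sample_cell] * np.exp(u[:, sample_geno]) * s[None, :]
    alpha = dispersion_at(m[:, sample_cell], base_design.dispersion_trend)
    counts = pd.DataFrame(
        _nb_draw(rng, mu, alpha), index=gene_ids, columns=meta.index
    )
    counts.index.name = "gene"
    genes = pd.DataFrame(
        {
            "class_label": labels,
            "m_flat_stable": m[:, 0],
            "m_flat_variable": m[:, 1],
            "m_slope_stable": m[:, 2],
            "m_slope_variable": m[:, 3],
            "module": "",
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    truth = SimTruth(
        genes=genes,
        genotype_effects=pd.DataFrame(u, index=gene_ids, columns=genotypes),
        latent_factors=pd.DataFrame(index=pd.Index([], dtype=object), columns=meta.index),
        size_factors=pd.Series(s, index=meta.index, name="size_factor"),
    )
    return counts, meta, truth


def simulate_gene_lengths(
    design: SimDesign, truth: SimTruth | None = None
) -> tuple[dict[str, int], GoMap]:
    """Log-normal gene lengths plus a random GO map.

    When ``length_bias_strength`` > 0 and a truth table is supplied, planted
    DE genes (any non-null class) are drawn longer on the log scale, so the
    probability that a long gene carries a planted DE flag increases with
    length — the bias the Wallenius enrichment corrects for.  In addition
    to random background categories, ``n_linked_go_categories`` categories
    are planted with members drawn preferentially (4:1 odds) from the
    non-null classes, giving downstream enrichment a true positive.
    """
    rng = np.random.default_rng(design.seed + 1)
    if truth is not None:
        gene_ids = list(truth.genes.index)
        flags = (truth.genes["class_label"] != "null").to_numpy(dtype=float)
    else:
        gene_ids = [f"gene{i + 1:05d}" for i in range(design.n_genes)]
        flags = np.zeros(design.n_genes)
    log_len = rng.normal(7.5, 0.7, size=len(gene_ids))
    log_len += design.length_bias_strength * flags
    lengths = {g: int(max(100, round(np.exp(v)))) for g, v in zip(gene_ids, log_len)}

    lo, hi = design.go_size_range
    go_map = GoMap()
    for k in range(design.n_go_categories):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(gene_ids))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        term = f"GO:{k + 1:07d}"
        for i in members:
            go_map.setdefault(gene_ids[i], set()).add(term)
    if truth is not None and flags.any():
        weights = np.where(flags > 0, 4.0, 1.0)
        weights = weights / weights.sum()
        for k in range(design.n_linked_go_categories):
            size = min(int(rng.integers(lo, hi + 1)), len(gene_ids))
            members = rng.choice(len(gene_ids), size=size, replace=False, p=weights)
            term = f"GO:{9000001 + k:07d}"
            for i in members:
                go_map.setdefault(gene_ids[i], set()).add(term)
    return lengths, go_map


def simulate_traits(
    trait_spec: Sequence[tuple[str, str, float, float]],
    meta: pd.DataFrame,
    truth: SimTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Traits driven by planted module latent factors.

    ``trait_spec`` rows are (trait name, module id, loading a, noise sd);
    each trait is a * factor + N(0, sd^2).  Binary 0/1 columns for origin
    (flat = 1) and treatment (variable = 1) are appended, matching the
    convention used for module-trait heatmaps.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name, module, a, noise_sd in trait_spec:
        if module not in truth.latent_factors.index:
            raise ValueError(f"trait {name!r} references unknown module {module!r}")
        f = truth.latent_factors.loc[module].to_numpy()
        out[name] = a * f + rng.normal(0.0, noise_sd, size=len(f))
    traits = pd.DataFrame(out, index=truth.latent_factors.columns)
    traits = traits.reindex(meta.index)
    traits["origin"] = (meta["origin"] == "flat").astype(int)
    traits["treatment"] = (meta["treatment"] == "variable").astype(int)
    return traits


#: Paper-scale cell means for the micromorphometric features
#: (origin, treatment) -> mean, with colony and residual noise SDs.
DEFAULT_MORPHO_SPEC: dict[str, dict] = {
    "coenosteum_width_mm": {
        "cells": {
            ("flat", "stable"): 0.18,
            ("flat", "variable"): 0.12,
            ("slope", "stable"): 0.17,
            ("slope", "variable"): 0.19,
        },
        "colony_sd": 0.01,
        "residual_sd": 0.02,
    },
    "spine_length_um": {
        "cells": {
            ("flat", "stable"): 93.0,
            ("flat", "variable"): 93.0,
            ("slope", "stable"): 109.0,
            ("slope", "variable"): 98.0,
        },
        "colony_sd": 4.0,
        "residual_sd": 8.0,
    },
    "rad_area_um2": {
        "cells": {
            ("flat", "stable"): 21.0,
            ("flat", "variable"): 13.0,
            ("slope", "stable"): 17.0,
            ("slope", "variable"): 17.0,
        },
        "colony_sd": 1.0,
        "residual_sd": 2.0,
    },
    "rads_per_spine": {
        "cells": {
            ("flat", "stable"): 30.0,
            ("flat", "variable"): 21.0,
            ("slope", "stable"): 18.0,
            ("slope", "variable"): 16.0,
        },
        "colony_sd": 1.5,
        "residual_sd": 3.0,
    },
}


def simulate_morphometrics(
    feature_spec: Mapping[str, Mapping] = DEFAULT_MORPHO_SPEC,
    n_per_cell: int = 4,
    n_colonies_per_origin: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Micromorphometric measurements with colony random intercepts.

    Each value is cell mean + colony effect (colonies nested within origin)
    + residual noise; ``n_per_cell`` measurements per origin x treatment
    cell are spread over the origin's colonies.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for feature, spec in feature_spec.items():
        cells = spec["cells"]
        colony_sd = spec.get("colony_sd", 0.0)
        residual_sd = spec.get("residual_sd", 0.0)
        colony_eff = {}
        for origin in ORIGINS:
            prefix = "F" if origin == "flat" else "S"
            for c in range(n_colonies_per_origin):
                colony_eff[f"{prefix}{c + 1:02d}"] = rng.normal(0.0, colony_sd)
        for (origin, treatment), mean in cells.items():
            prefix = "F" if origin == "flat" else "S"
            for i in range(n_per_cell):
                colony = f"{prefix}{(i % n_colonies_per_origin) + 1:02d}"
                value = mean + colony_eff[colony] + rng.normal(0.0, residual_sd)
                rows.append(
                    {
                        "feature": feature,
                        "value": value,
                        "colony": colony,
                        "origin": origin,
                        "treatment": treatment,
                    }
                )
    return pd.DataFrame(rows)


def simulate_pco2_series(
    mean_level: float,
    diel_amplitude: float,
    days: int = 7,
    noise_sd: float = 0.0,
    cadence_minutes: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Sinusoidal diel pCO2 series (uatm) sampled at a fixed cadence.

    ``diel_amplitude`` is peak-to-trough; the series covers whole days.
    """
    rng = np.random.default_rng(seed)
    n = int(days * 24 * 60 / cadence_minutes)
    t_days = np.arange(n) * cadence_minutes / (24.0 * 60.0)
    values = mean_level + 0.5 * diel_amplitude * np.sin(2 * np.pi * t_days)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n)
    return pd.Series(values, index=pd.Index(t_days, name="day"), name="pco2_uatm")


def diel_amplitude_summary(series: pd.Series) -> float:
    """Mean over days of the daily range (max - min)."""
    day = np.floor(series.index.to_numpy()).astype(int)
    grouped = series.groupby(day)
    return float((grouped.max() - grouped.min()).mean())
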