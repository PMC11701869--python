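"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from frontloadseq.de_glmm import fit_all_genes
from frontloadseq.frontloading import classify_table
from frontloadseq.preprocess import estimate_dispersion_trend, size_factors
from frontloadseq.simulate import (
    SimDesign,
    make_sample_meta,
    simulate_counts,
    simulate_frontload_validation,
)


@pytest.fixture(scope="session")
def meta48() -> pd.DataFrame:
    """12 colonies per origin x 2 treatments, one fragment each."""
    return make_sample_meta(SimDesign(n_genes=10))


@pytest.fixture(scope="session")
def small_run():
    """A small full simulation with planted classes and modules."""
    design = SimDesign(
        n_genes=400,
        seed=20,
        module_spec=[(60, 0.8), (60, 0.8)],
    )
    counts, meta, truth = simulate_counts(design)
    return design, counts, meta, truth


@pytest.fixture(scope="session")
def frontload_validation_run():
    """Classifier validation at study-scale conditions.

    200 genes, 10% planted frontloaded at 2-fold effects, colony SD 0.3,
    and the 46-sample analysis set (one flat colony excluded, mirroring
    the outlier-driven removal of one genotype's two fragments).
    """
    counts, meta, truth = simulate_frontload_validation(
        n_genes=200, frontload_prop=0.1, effect=2.0, genotype_sd=0.3, seed=101
    )
    meta = meta[meta["genotype"] != "F12"]
    counts = counts[meta.index]
    sf = size_factors(counts)
    trend = estimate_dispersion_trend(counts, sf)
    de_table = fit_all_genes(counts, meta, trend.trended(), sf)
    records = classify_table(de_table)
    return truth, de_table, records


def planted_blocks(
    seed: int,
    n_blocks: int = 3,
    block_size: int = 60,
    n_noise: int = 50,
    within_cor: float = 0.8,
    n_samples: int = 46,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expression with latent-factor blocks plus independent noise genes."""
    rng = np.random.default_rng(seed)
    lam = np.sqrt(within_cor / (1.0 - within_cor))
    rows, labels = [], []
    for b in range(n_blocks):
        f = rng.normal(size=n_samples)
        for _ in range(block_size):
            rows.append(lam * f + rng.normal(size=n_samples))
            labels.append(b)
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append(-1)
    expr = pd.DataFrame(rows, index=[f"g{i:04d}" for i in range(len(rows))])
    return expr, np.array(labels)
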