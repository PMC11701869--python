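"""Transcriptional frontloading classification.

A gene is "frontloaded" when corals native to the variable habitat (reef
flat) hold its expression constitutively high instead of inducing it:

* control ratio  C = m(flat, stable) / m(slope, stable) > 1
  (higher baseline in flat-origin corals under the common-garden stable
  treatment), and
* fold-change ratio  F = [m(flat, variable) / m(flat, stable)] /
  [m(slope, variable) / m(slope, stable)] < 1
  (a smaller treatment response in flat-origin corals).

Both ratios are computed from model-estimated cell means, never from raw
cell averages.  Strict inequalities: a gene sitting exactly on either
boundary is not frontloaded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de_glmm import CELL_ORDER, TERMS


@dataclass
class FrontloadRecord:
    gene: str
    control_ratio: float
    foldchange_ratio: float
    frontloaded: bool
    classifiable: bool = True


def classify_frontloaded(
    means, gene: str = "", prose_variant: bool = False
) -> FrontloadRecord:
    """Classify one gene from its four estimated cell means.

    ``means`` is indexable by the cell names (flat_stable, flat_variable,
    slope_stable, slope_variable) or a length-4 sequence in that order.
    ``prose_variant`` switches the control ratio's numerator to the
    flat-origin *variable* cell (an alternative published reading of the
    criterion); the default compares the two stable cells.
    """
    if isinstance(means, (list, tuple, np.ndarray)):
        means = pd.Series(np.asarray(means, dtype=float), index=CELL_ORDER)
    m = means.reindex(CELL_ORDER).astype(float)
    if m.isna().any() or (m <= 0).any():
        return FrontloadRecord(gene, np.nan, np.nan, False, classifiable=False)
    fs, fv, ss, sv = (m[c] for c in CELL_ORDER)
    numerator = fv if prose_variant else fs
    control = numerator / ss
    foldchange = (fv / fs) / (sv / ss)
    frontloaded = bool(control > 1.0 and foldchange < 1.0)
    return FrontloadRecord(gene, float(control), float(foldchange), frontloaded)


def classify_table(de_table: pd.DataFrame, prose_variant: bool = False) -> pd.DataFrame:
    """Frontloading records for every converged gene in a DE table."""
    mean_cols = [f"mean_{c}" for c in CELL_ORDER]
    rows = []
    for gene, row in de_table.iterrows():
        means = pd.Series(row[mean_cols].to_numpy(dtype=float), index=CELL_ORDER)
        if not row.get("converged", True):
            means[:] = np.nan
        rec = classify_frontloaded(means, gene=gene, prose_variant=prose_variant)
        rows.append(
            {
                "gene": gene,
                "control_ratio": rec.control_ratio,
                "foldchange_ratio": rec.foldchange_ratio,
                "frontloaded": rec.frontloaded,
                "classifiable": rec.classifiable,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def frontload_summary(records: pd.DataFrame) -> tuple[int, float]:
    """(number frontloaded, proportion of classifiable genes)."""
    if len(records) == 0:
        return 0, 0.0
    classifiable = records["classifiable"].to_numpy(dtype=bool)
    n_front = int(records.loc[classifiable, "frontloaded"].sum())
    denom = int(classifiable.sum())
    return n_front, (n_front / denom if denom else 0.0)


def annotate_gene_set(
    records: pd.DataFrame,
    de_table: pd.DataFrame,
    gene_set: dict[str, str],
    q_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Cross-reference a curated gene set against DE and frontloading calls.

    ``gene_set`` maps a curated name (e.g., a biomineralisation-related
    protein) to a gene id in the analyzed dataset.  Returns a per-member
    table plus the list of ids that did not match the dataset; fractions
    reported by callers should use matched genes as the denominator.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    matched_rows = []
    unmatched = []
    for name, gene in gene_set.items():
        if gene not in records.index or gene not in de_table.index:
            unmatched.append(gene)
            continue
        row = {
            "name": name,
            "gene": gene,
            "frontloaded": bool(records.loc[gene, "frontloaded"]),
            "control_ratio": records.loc[gene, "control_ratio"],
            "foldchange_ratio": records.loc[gene, "foldchange_ratio"],
        }
        for term in TERMS:
            q = de_table.loc[gene, f"q_{term}"]
            row[f"de_{term}"] = bool(q < q_cutoff) if np.isfinite(q) else False
            beta = de_table.loc[gene, f"beta_{term}"]
            row[f"direction_{term}"] = "up" if beta > 0 else "down"
        matched_rows.append(row)
    table = pd.DataFrame(matched_rows)
    if len(table):
        table = table.set_index("name")
    return table, unmatched


def gene_set_summary(table: pd.DataFrame) -> dict:
    """Counts and fractions over the matched members of a curated set."""
    n = len(table)
    n_front = int(table["frontloaded"].sum()) if n else 0
    out = {
        "n_matched": n,
        "n_frontloaded": n_front,
        "fraction_frontloaded": (n_front / n) if n else 0.0,
    }
    for term in TERMS:
        out[f"n_de_{term}"] = int(table[f"de_{term}"].sum()) if n else 0
    return out
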