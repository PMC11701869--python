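"""Readers and writers for the pipeline's on-disk formats.

Counts travel as TSV (genes x samples, first column gene ids), sample
metadata and traits as CSV with a header, gene structure as GFF3 (parsed
with gffutils) or a two-column TSV, and the gene->GO map as a two-column
TSV.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger("frontloadseq")

ORIGINS = ("flat", "slope")
TREATMENTS = ("stable", "variable")

_GO_RE = re.compile(r"^GO:\d{7}$")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix from TSV.

    The first column holds gene ids, the header row sample ids.  Negative
    or non-integer entries, duplicate gene ids and ragged rows are errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.split("\t")
        ncol = len(cols)
        for lineno, line in enumerate(fh, start=2):
            n = len(line.rstrip("\n").split("\t"))
            if n != ncol:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({n} fields, expected {ncol})"
                )
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene id {dup[0]!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric count entries")
    if np.any(values < 0):
        raise ValueError(f"{path}: negative count entries")
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: non-integer count entries")
    df = df.astype(np.int64)
    df.index.name = "gene"
    return df


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, origin, treatment, genotype) CSV."""
    meta = pd.read_csv(path, dtype=str)
    required = {"sample_id", "origin", "treatment", "genotype"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    bad_origin = set(meta["origin"]) - set(ORIGINS)
    if bad_origin:
        raise ValueError(f"{path}: unknown origin levels {sorted(bad_origin)}")
    bad_treat = set(meta["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise ValueError(f"{path}: unknown treatment levels {sorted(bad_treat)}")
    # genotypes are nested within origin: a colony id may not span origins
    span = meta.groupby("genotype")["origin"].nunique()
    crossed = span[span > 1]
    if len(crossed):
        raise ValueError(
            f"{path}: genotype {crossed.index[0]!r} appears in both origins"
        )
    return meta.set_index("sample_id", drop=False)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def _exon_union_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered length of half-open intervals."""
    total = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start >= last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """Read per-gene lengths from a GFF3 file or a two-column TSV.

    GFF3 mode reports, for each gene, the length of the union of all exon
    intervals across its transcripts (robust to isoform redundancy).  GFF3
    coordinates are 1-based inclusive; a gene with no exon features falls
    back to its own span with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or _looks_like_gff(path):
        return _lengths_from_gff3(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene, length = parts
            length_i = int(length)
            if length_i <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {gene}")
            lengths[gene] = length_i
    return lengths


def _looks_like_gff(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return len(line.split("\t")) == 9
    return False


def _lengths_from_gff3(path: Path) -> dict[str, int]:
    # validate line shapes up front so we can report line numbers
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    lengths: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)  # to half-open 0-based
            for e in db.children(gene, featuretype="exon")
        ]
        if exons:
            lengths[gene.id] = _exon_union_length(exons)
        else:
            warnings.warn(
                f"gene {gene.id} has no exon features; using transcript span",
                stacklevel=2,
            )
            lengths[gene.id] = gene.end - gene.start + 1
    return lengths


def write_gene_lengths(lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, length in lengths.items():
            fh.write(f"{gene}\t{length}\n")


class GoMap(dict):
    """gene id -> set of GO ids; unannotated genes map to the empty set."""

    def __missing__(self, key):  # noqa: D105
        return set()


def read_go_map(path: str | Path) -> GoMap:
    """Read a two-column gene-to-GO-term TSV.

    Multiple rows per gene accumulate; rows whose term does not match
    ``GO:`` + 7 digits are skipped with a warning.  Genes absent from the
    file are legal and query as unannotated.
    """
    result = GoMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene, term = parts
            if not _GO_RE.match(term):
                warnings.warn(
                    f"{path}:{lineno}: malformed GO id {term!r}, row skipped",
                    stacklevel=2,
                )
                continue
            result.setdefault(gene, set()).add(term)
    return result


def write_go_map(go_map: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in go_map:
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Samples x traits CSV, first column sample ids."""
    return pd.read_csv(path, index_col=0)


def read_morpho_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"feature", "value", "colony", "origin", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing morphometric columns {sorted(missing)}")
    if not np.isfinite(df["value"]).all():
        raise ValueError(f"{path}: non-finite morphometric values")
    return df


def write_manifest(path: str | Path, config: dict, seed: int, tables: dict[str, int]) -> None:
    """One JSON manifest per run: config, seed and output row counts."""
    import frontloadseq

    payload = {
        "package": "frontloadseq",
        "version": frontloadseq.__version__,
        "seed": seed,
        "config": config,
        "tables": tables,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
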