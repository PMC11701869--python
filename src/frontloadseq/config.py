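"""Pipeline configuration.

A single flat configuration object carries every tunable threshold of the
pipeline: the expression filters, the FDR level, the co-expression network
parameters and the GO-enrichment cutoff.  It can be loaded from a flat YAML
file whose keys mirror the dataclass fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and parameters for the full analysis pipeline.

    Parameters
    ----------
    pover_p
        Minimum proportion of samples that must reach ``pover_a`` counts for
        a gene to pass the low-expression filter.
    pover_a
        Count threshold of the pOverA filter.
    q_cutoff
        FDR level below which a gene is called differentially expressed.
    soft_power
        Exponent applied to the signed co-expression similarity.
    min_module_size
        Smallest number of genes a detected co-expression module may have.
    merge_cut_height
        Eigengene dissimilarity (1 - r) below which modules are merged;
        0.15 corresponds to merging modules whose eigengenes correlate at
        r > 0.85.
    deep_split
        Sensitivity level (0-4) of the dynamic hybrid tree cut.
    go_p_cutoff
        Over-representation p-value below which a GO term is reported as
        enriched.
    rng_seed
        Seed for every stochastic stage of the pipeline.
    frontload_prose_variant
        If True, the frontloading control ratio compares the flat-origin
        *variable*-treatment cell against the slope-origin stable cell (an
        alternative reading of the published criterion); the default uses
        the stable/stable ratio.
    """

    pover_p: float = 0.25
    pover_a: float = 10
    q_cutoff: float = 0.05
    soft_power: int = 5
    min_module_size: int = 30
    merge_cut_height: float = 0.15
    deep_split: int = 1
    go_p_cutoff: float = 0.05
    rng_seed: int = 0
    frontload_prose_variant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pover_p <= 1.0:
            raise ValueError(f"pover_p must be in [0, 1], got {self.pover_p}")
        if self.pover_a < 0:
            raise ValueError(f"pover_a must be >= 0, got {self.pover_a}")
        if not 0.0 < self.q_cutoff < 1.0:
            raise ValueError(f"q_cutoff must be in (0, 1), got {self.q_cutoff}")
        if self.soft_power < 1 or int(self.soft_power) != self.soft_power:
            raise ValueError(f"soft_power must be a positive integer, got {self.soft_power}")
        if self.min_module_size < 1:
            raise ValueError(f"min_module_size must be positive, got {self.min_module_size}")
        if not 0.0 <= self.merge_cut_height <= 1.0:
            raise ValueError(
                f"merge_cut_height must be in [0, 1], got {self.merge_cut_height}"
            )
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ValueError(f"deep_split must be in 0..4, got {self.deep_split}")
        if not 0.0 < self.go_p_cutoff <= 1.0:
            raise ValueError(f"go_p_cutoff must be in (0, 1], got {self.go_p_cutoff}")
        if self.rng_seed < 0:
            raise ValueError(f"rng_seed must be non-negative, got {self.rng_seed}")

    @property
    def eigengene_cor_threshold(self) -> float:
        """Modules whose eigengenes correlate above this are merged."""
        return 1.0 - self.merge_cut_height

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a configuration from a flat YAML mapping.

        Unknown keys raise, so typos in a config file fail loudly.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
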