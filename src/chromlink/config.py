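"""Pipeline configuration.

Every numeric threshold printed in the methods note is a named field here,
never a literal in analysis code.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

#: canonical lineage order used everywhere: ectoderm, endoderm, mesoderm
LINEAGES = ("ect", "end", "mes")

#: default zone-of-influence grid (bp), spanning typical TAD size ranges
DEFAULT_GRID = (20_000, 40_000, 80_000, 120_000, 160_000, 200_000, 300_000, 400_000)


@dataclass
class Config:
    """All tunable thresholds of the pipeline with their defaults.

    Attributes
    ----------
    acc_window, meth_window
        Fixed window widths (bp) for accessibility (100) and methylation (500).
    d_high, d_low
        Dominance-index thresholds: ``Dom >= d_high`` calls a differential
        gene/region, ``Dom <= d_low`` a similar one. ``1/3`` is perfect
        evenness, so ``d_low`` slightly above it captures "almost even".
    deg_min_expr
        Expression floor (log2 RPKM) the dominant lineage must exceed for a
        DEG call.
    seg_min_expr
        Floor (log2 RPKM) every lineage must exceed for a SEG call.
    ha_cutoff
        Mean accessibility level splitting similarly accessible regions into
        high-accessible (HA, > cutoff) and low-accessible (LA).
    shmr_ceiling
        Mean methylation below which an even window counts as similarly
        hypomethylated.
    min_reads, min_reads_per_gc
        Window QC: per-lineage read count must exceed ``min_reads`` and the
        reads-per-GC-dinucleotide ratio must exceed ``min_reads_per_gc``.
    qc_variant
        "cv" (default; coefficient-of-variation balance filters) or
        "literal" (the printed inequalities, kept for auditability).
    meth_polarity
        "hypo" (default; dominance computed on 1 - M so the dominant lineage
        is the most hypomethylated) or "literal" (dominance on M itself).
    vicinity_grid
        Candidate vicinity half-widths (bp) for the zone-of-influence scan.
    profile_bin
        Bin width (bp) of accessibility-index profiles.
    cluster_vicinity
        Half-width (bp) used when asking whether regions of one class cluster
        around regions of another.
    expr_thresholds
        log2 RPKM thresholds for the transcriptome-architecture sweep.
    n_perm, seed
        Permutation count and base seed for all permutation tests.
    """

    acc_window: int = 100
    meth_window: int = 500
    d_high: float = 0.6
    d_low: float = 0.34
    deg_min_expr: float = 2.0
    seg_min_expr: float = 0.0
    ha_cutoff: float = 0.35
    shmr_ceiling: float = 0.5
    min_reads: int = 25
    min_reads_per_gc: float = 2.0
    qc_variant: str = "cv"
    meth_polarity: str = "hypo"
    vicinity_grid: Sequence[int] = field(default_factory=lambda: list(DEFAULT_GRID))
    profile_bin: int = 5_000
    cluster_vicinity: int = 10_000
    expr_thresholds: Sequence[float] = field(
        default_factory=lambda: [-3, -2, -1, 0, 1, 2, 3]
    )
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.d_high > self.d_low >= 1 / 3):
            raise ValueError(
                f"require d_high > d_low >= 1/3, got {self.d_high}, {self.d_low}"
            )
        grid = list(self.vicinity_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("vicinity_grid must be strictly increasing")
        if self.qc_variant not in ("cv", "literal"):
            raise ValueError(f"unknown qc_variant {self.qc_variant!r}")
        if self.meth_polarity not in ("hypo", "literal"):
            raise ValueError(f"unknown meth_polarity {self.meth_polarity!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
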