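"""Window-level QC and dominance-based calling of chromatin regions.

Accessibility is measured in non-overlapping 100-bp windows as the fraction
of methylated GpC dinucleotides (NOMe-seq: a methylated GpC marks open
chromatin); endogenous CpG methylation uses wider 500-bp windows. The same
dominance statistic used for expression classifies each window as
differential (one lineage dominates) or similar (even across lineages):

* DAR / SAR  - differentially / similarly accessible region,
  with SARs split into high- (HA) and low-accessible (LA) at 35% mean level;
* DhMR / ShMR - differentially / similarly hypomethylated region,
  dominance computed on 1 - M by default so the dominant lineage is the
  most hypomethylated, and ShMRs additionally requiring low mean
  methylation.

Each qualifying window is reported as one region; adjacent qualifying
windows can optionally be merged, but region counts are window-resolution
by default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import Config, LINEAGES
from .expression import THRESHOLD_ATOL, dominance
from .stats import make_report

logger = logging.getLogger("chromlink")

READ_COLS = [f"reads_{lin}" for lin in LINEAGES]
TOTAL_COLS = [f"total_{lin}" for lin in LINEAGES]
METH_COLS = [f"meth_{lin}" for lin in LINEAGES]
LEVEL_COLS = [f"level_{lin}" for lin in LINEAGES]


@dataclass
class QcReport:
    """Window counts surviving each successive QC filter."""

    n_windows_in: int
    n_pass_coverage: int
    n_pass_coverage_balance: int
    n_pass_gc_balance: int
    variant: str

    def to_dict(self) -> dict:
        return asdict(self)


def window_levels(windows: pd.DataFrame) -> pd.DataFrame:
    """Attach per-lineage signal levels: methylated / total dinucleotides.

    Windows where any lineage has zero dinucleotides have no defined level
    and are dropped (count logged).
    """
    df = windows.copy()
    totals = df[TOTAL_COLS].to_numpy(dtype=float)
    defined = (totals > 0).all(axis=1)
    if (~defined).any():
        logger.info("dropping %d windows with zero dinucleotide totals", int((~defined).sum()))
        df = df[defined].reset_index(drop=True)
        totals = totals[defined]
    meth = df[METH_COLS].to_numpy(dtype=float)
    levels = meth / totals
    for i, col in enumerate(LEVEL_COLS):
        df[col] = levels[:, i]
    return df


def qc_filter(
    windows: pd.DataFrame,
    config: Config | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Three-stage window QC.

    Filter 1 (coverage): every lineage needs reads > ``min_reads`` (25) and
    reads per dinucleotide > ``min_reads_per_gc`` (2).

    Filters 2-3 (balance across lineages) come in two variants. The
    "literal" variant applies the printed inequalities
    ``|max|cov_i - cov_j| - mean(cov)| < std(cov)`` (and the 3-sigma GC
    analogue); as stated these reject perfectly balanced windows (the
    left side equals the mean while the std is 0), so the default "cv"
    variant reads the requirement "variability ... less than one standard
    deviation over mean" as a coefficient of variation: std/mean < 1 for
    coverage and std/mean < 3 for GC counts, sample (n-1) standard
    deviation.
    """
    cfg = config or Config()
    df = windows.reset_index(drop=True)
    reads = df[READ_COLS].to_numpy(dtype=float)
    totals = df[TOTAL_COLS].to_numpy(dtype=float)
    if (reads < 0).any() or (totals < 0).any():
        raise ValueError("negative counts in window table")
    n_in = len(df)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(totals > 0, reads / np.where(totals > 0, totals, 1), np.inf)
    pass1 = (reads > cfg.min_reads).all(axis=1) & (ratio > cfg.min_reads_per_gc).all(axis=1)

    def _balance(mat: np.ndarray, sigma_mult: float) -> np.ndarray:
        mean = mat.mean(axis=1)
        std = mat.std(axis=1, ddof=1)
        if cfg.qc_variant == "cv":
            with np.errstate(invalid="ignore", divide="ignore"):
                cv = np.where(mean > 0, std / np.where(mean > 0, mean, 1), np.inf)
            return cv < sigma_mult
        # literal: |max pairwise difference - mean| < sigma_mult * std
        max_diff = mat.max(axis=1) - mat.min(axis=1)
        return np.abs(max_diff - mean) < sigma_mult * std

    pass2 = pass1 & _balance(reads, 1.0)
    pass3 = pass2 & _balance(totals, 3.0)

    report = QcReport(
        n_windows_in=n_in,
        n_pass_coverage=int(pass1.sum()),
        n_pass_coverage_balance=int(pass2.sum()),
        n_pass_gc_balance=int(pass3.sum()),
        variant=cfg.qc_variant,
    )
    logger.info(
        "QC (%s): %d -> %d -> %d -> %d windows",
        cfg.qc_variant, n_in, report.n_pass_coverage,
        report.n_pass_coverage_balance, report.n_pass_gc_balance,
    )
    return df[pass3].reset_index(drop=True), report


def _merge_adjacent(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge book-ended windows of identical class and lineage."""
    if len(regions) == 0:
        return regions
    out = []
    for (chrom, cls, lin), sub in regions.groupby(
        ["chrom", "region_class", "lineage"], sort=False
    ):
        sub = sub.sort_values("start")
        run_start, run_end, doms, levels = None, None, [], []
        for row in sub.itertuples():
            if run_start is None:
                run_start, run_end = row.start, row.end
                doms, levels = [row.dominance], [row.mean_level]
            elif row.start == run_end:
                run_end = row.end
                doms.append(row.dominance)
                levels.append(row.mean_level)
            else:
                out.append((chrom, run_start, run_end, cls, lin,
                            float(np.mean(doms)), float(np.mean(levels))))
                run_start, run_end = row.start, row.end
                doms, levels = [row.dominance], [row.mean_level]
        out.append((chrom, run_start, run_end, cls, lin,
                    float(np.mean(doms)), float(np.mean(levels))))
    return pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "region_class", "lineage", "dominance", "mean_level"],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)


def call_accessibility_regions(
    windows: pd.DataFrame,
    config: Config | None = None,
    merge: bool = False,
) -> pd.DataFrame:
    """Call DARs and SARs from QC-passed accessibility windows.

    Da = max(A_i)/sum(A_i) over the three lineage levels. Da >= d_high
    (0.6) makes the window a DAR of the argmax lineage; Da <= d_low (0.34)
    a SAR, split into SAR_HA (mean level > 0.35) and SAR_LA otherwise.
    Windows in between are not reported; all-zero windows are skipped.
    """
    cfg = config or Config()
    df = windows if set(LEVEL_COLS) <= set(windows.columns) else window_levels(windows)
    levels = df[LEVEL_COLS].to_numpy(dtype=float)
    da = dominance(levels)
    mean_level = levels.mean(axis=1)
    argmax = np.array(LINEAGES)[np.argmax(levels, axis=1)]

    defined = ~np.isnan(da)
    is_dar = defined & (da >= cfg.d_high - THRESHOLD_ATOL)
    is_sar = defined & (da <= cfg.d_low + THRESHOLD_ATOL)
    cls = np.full(len(df), "", dtype=object)
    lin = np.full(len(df), "all", dtype=object)
    cls[is_dar] = "DAR"
    lin[is_dar] = argmax[is_dar]
    cls[is_sar & (mean_level > cfg.ha_cutoff)] = "SAR_HA"
    cls[is_sar & (mean_level <= cfg.ha_cutoff)] = "SAR_LA"

    keep = cls != ""
    regions = pd.DataFrame(
        {
            "chrom": df.loc[keep, "chrom"].to_numpy(),
            "start": df.loc[keep, "start"].to_numpy(),
            "end": df.loc[keep, "end"].to_numpy(),
            "region_class": cls[keep],
            "lineage": lin[keep],
            "dominance": da[keep],
            "mean_level": mean_level[keep],
        }
    )
    logger.info(
        "called %d DARs, %d SARs from %d windows",
        int(is_dar.sum()), int((regions["region_class"] != "DAR").sum()), len(df),
    )
    if merge:
        regions = _merge_adjacent(regions)
    return regions.sort_values(["chrom", "start"]).reset_index(drop=True)


def call_methylation_regions(
    windows: pd.DataFrame,
    config: Config | None = None,
    merge: bool = False,
) -> pd.DataFrame:
    """Call DhMRs and ShMRs from 500-bp CpG methylation windows.

    M_i is the methylated CpG fraction per lineage. Under the default
    "hypo" polarity dominance is computed on h_i = 1 - M_i, so the dominant
    lineage of a DhMR is the most hypomethylated one; an ShMR requires
    evenness (Dom(h) <= d_low) AND low methylation (mean M below
    ``shmr_ceiling``). The "literal" polarity applies dominance to M_i
    unchanged.
    """
    cfg = config or Config()
    df = windows if set(LEVEL_COLS) <= set(windows.columns) else window_levels(windows)
    m = df[LEVEL_COLS].to_numpy(dtype=float)
    signal = 1.0 - m if cfg.meth_polarity == "hypo" else m
    dom = dominance(signal)
    mean_m = m.mean(axis=1)
    argmax = np.array(LINEAGES)[np.argmax(signal, axis=1)]

    defined = ~np.isnan(dom)
    is_dhmr = defined & (dom >= cfg.d_high - THRESHOLD_ATOL)
    is_shmr = defined & (dom <= cfg.d_low + THRESHOLD_ATOL) & (mean_m < cfg.shmr_ceiling)
    cls = np.full(len(df), "", dtype=object)
    lin = np.full(len(df), "all", dtype=object)
    cls[is_dhmr] = "DhMR"
    lin[is_dhmr] = argmax[is_dhmr]
    cls[is_shmr] = "ShMR"

    keep = cls != ""
    regions = pd.DataFrame(
        {
            "chrom": df.loc[keep, "chrom"].to_numpy(),
            "start": df.loc[keep, "start"].to_numpy(),
            "end": df.loc[keep, "end"].to_numpy(),
            "region_class": cls[keep],
            "lineage": lin[keep],
            "dominance": dom[keep],
            "mean_level": mean_m[keep],
        }
    )
    logger.info(
        "called %d DhMRs, %d ShMRs from %d windows (polarity=%s)",
        int(is_dhmr.sum()), int(is_shmr.sum()), len(df), cfg.meth_polarity,
    )
    if merge:
        regions = _merge_adjacent(regions)
    return regions.sort_values(["chrom", "start"]).reset_index(drop=True)


# --- clustering of one region set around another --------------------------

def _centres(regions: pd.DataFrame) -> pd.DataFrame:
    c = regions.copy()
    c["centre"] = (c["start"] + c["end"]) // 2
    return c


def _fraction_near(a: pd.DataFrame, b: pd.DataFrame, vicinity: int) -> float:
    """Fraction of A centres with at least one B centre within ``vicinity``."""
    if len(a) == 0:
        return 0.0
    hits = 0
    for chrom, sub_a in a.groupby("chrom", sort=False):
        sub_b = b[b["chrom"] == chrom]
        if len(sub_b) == 0:
            continue
        bc = np.sort(sub_b["centre"].to_numpy())
        ac = sub_a["centre"].to_numpy()
        idx = np.searchsorted(bc, ac)
        left = np.where(idx > 0, ac - bc[np.clip(idx - 1, 0, len(bc) - 1)], np.inf)
        right = np.where(idx < len(bc), bc[np.clip(idx, 0, len(bc) - 1)] - ac, np.inf)
        hits += int(np.sum(np.minimum(left, right) <= vicinity))
    return hits / len(a)


def interval_jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Base-pair Jaccard index of two interval sets (per set pre-unioned)."""

    def _union(df: pd.DataFrame, chrom: str) -> list[tuple[int, int]]:
        sub = df[df["chrom"] == chrom].sort_values("start")
        merged: list[list[int]] = []
        for row in sub.itertuples():
            if merged and row.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], row.end)
            else:
                merged.append([row.start, row.end])
        return [(s, e) for s, e in merged]

    chroms = sorted(set(a["chrom"]) | set(b["chrom"]))
    inter = union = 0
    for chrom in chroms:
        ua, ub = _union(a, chrom), _union(b, chrom)
        union += sum(e - s for s, e in ua) + sum(e - s for s, e in ub)
        i = j = 0
        while i < len(ua) and j < len(ub):
            s = max(ua[i][0], ub[j][0])
            e = min(ua[i][1], ub[j][1])
            if e > s:
                inter += e - s
            if ua[i][1] < ub[j][1]:
                i += 1
            else:
                j += 1
    union -= inter
    return inter / union if union else 0.0


def cluster_fraction(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    vicinity: int = 10_000,
    n_perm: int = 1000,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> dict:
    """How often do regions of class B cluster around regions of class A?

    Reports the fraction of A-region centres with at least one B centre
    within ``vicinity`` bp, the base-pair Jaccard of the two interval sets,
    and a permutation test whose null circularly shifts B's positions
    uniformly within each chromosome.
    """
    a, b = _centres(set_a), _centres(set_b)
    if len(a) == 0 or len(b) == 0:
        logger.warning("cluster_fraction on empty region set")
        return {"fraction": 0.0, "jaccard": 0.0, "report": None}
    if chrom_sizes is None:
        chrom_sizes = {
            chrom: int(
                max(
                    a.loc[a["chrom"] == chrom, "end"].max() if (a["chrom"] == chrom).any() else 0,
                    b.loc[b["chrom"] == chrom, "end"].max() if (b["chrom"] == chrom).any() else 0,
                )
            )
            for chrom in set(a["chrom"]) | set(b["chrom"])
        }
    observed = _fraction_near(a, b, vicinity)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shifted = b.copy()
        for chrom, size in chrom_sizes.items():
            mask = shifted["chrom"] == chrom
            if mask.any() and size > 0:
                shift = int(rng.integers(0, size))
                shifted.loc[mask, "centre"] = (shifted.loc[mask, "centre"] + shift) % size
        null[i] = _fraction_near(a, shifted, vicinity)
    report = make_report("cluster_fraction", observed, null, direction="ge", seed=seed)
    return {
        "fraction": observed,
        "jaccard": interval_jaccard(set_a, set_b),
        "report": report,
    }
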