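"""Linear-genome and TAD-level architecture statistics.

Developmental genes tend to sit isolated in gene deserts while housekeeping
genes cluster; this module quantifies that with nearest-expressed-TSS
distances under an expression-threshold sweep, per-TAD gene densities, a
label-shuffling test of DEG/SEG co-occurrence within TADs, and a CG-rich
promoter classification.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import LINEAGES
from .expression import EXPR_COLS
from .stats import PermutationReport, make_report

logger = logging.getLogger("chromlink")


def nearest_expressed_distance(
    annotation: pd.DataFrame,
    expr: pd.DataFrame,
    threshold: float,
) -> pd.DataFrame:
    """Distance from each retained gene's TSS to its nearest retained neighbour.

    A gene is retained when its maximal lineage expression (log2 RPKM)
    exceeds ``threshold``; the filter applies to the neighbour set as well,
    so raising the threshold can only push neighbours further away. Genes
    are ordered by TSS per chromosome and d_i is the minimum of the two
    adjacent gaps (one gap at chromosome ends). A chromosome's only
    retained gene gets d = NaN.

    Returns gene_id, d, threshold.
    """
    retained_ids = set(
        expr.loc[expr[EXPR_COLS].max(axis=1) > threshold, "gene_id"]
    )
    genes = annotation[annotation["gene_id"].isin(retained_ids)]
    if len(genes) == 0:
        logger.warning("no genes retained at threshold %s", threshold)
        return pd.DataFrame(columns=["gene_id", "d", "threshold"])
    parts = []
    for _, sub in genes.groupby("chrom", sort=False):
        sub = sub.sort_values("tss", kind="mergesort")
        tss = sub["tss"].to_numpy(dtype=float)
        if len(tss) == 1:
            d = np.array([np.nan])
        else:
            gaps = np.diff(tss)
            left = np.concatenate([[np.inf], gaps])
            right = np.concatenate([gaps, [np.inf]])
            d = np.minimum(left, right)
        parts.append(pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(), "d": d}))
    out = pd.concat(parts, ignore_index=True)
    out["threshold"] = threshold
    return out


def distance_sweep(annotation, expr, thresholds) -> pd.DataFrame:
    """Nearest-distance table stacked over an expression-threshold grid."""
    return pd.concat(
        [nearest_expressed_distance(annotation, expr, t) for t in thresholds],
        ignore_index=True,
    )


def compare_distances(deg_d, seg_d) -> dict:
    """Two-sided Mann-Whitney comparison of two distance samples.

    Returns the U statistic, p-value and both medians. Degenerate all-tied
    input yields p = 1 with a warning.
    """
    deg_d = np.asarray(deg_d, dtype=float)
    seg_d = np.asarray(seg_d, dtype=float)
    deg_d, seg_d = deg_d[~np.isnan(deg_d)], seg_d[~np.isnan(seg_d)]
    if len(deg_d) == 0 or len(seg_d) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([deg_d, seg_d])
    if np.all(pooled == pooled[0]):
        logger.warning("ties-only input to compare_distances; p = 1")
        return {
            "statistic": float(len(deg_d) * len(seg_d) / 2),
            "p_value": 1.0,
            "median_a": float(np.median(deg_d)),
            "median_b": float(np.median(seg_d)),
        }
    res = sps.mannwhitneyu(deg_d, seg_d, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_a": float(np.median(deg_d)),
        "median_b": float(np.median(seg_d)),
    }


def assign_genes_to_tads(tads: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """tad_id per gene by half-open containment of the TSS; NaN when outside all TADs."""
    out = pd.Series(np.nan, index=genes.index, dtype=object)
    for chrom, sub in tads.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["tad_id"].to_numpy()
        mask = genes["chrom"] == chrom
        tss = genes.loc[mask, "tss"].to_numpy()
        pos = np.searchsorted(starts, tss, side="right") - 1
        inside = (pos >= 0) & (tss < ends[np.clip(pos, 0, len(ends) - 1)])
        vals = np.where(inside, ids[np.clip(pos, 0, len(ids) - 1)], None)
        out.loc[mask] = vals
    return out


def tad_summaries(
    tads: pd.DataFrame,
    genes_with_classes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-TAD gene counts, DEG/SEG counts and density per 100 kB.

    ``genes_with_classes`` carries gene_id, chrom, tss, class_label. TSS
    exactly on a TAD boundary belongs to the TAD whose half-open interval
    contains it. Density = n_genes * 100000 / TAD length.
    """
    genes = genes_with_classes.copy()
    genes["tad_id"] = assign_genes_to_tads(tads, genes)
    inside = genes.dropna(subset=["tad_id"])
    is_deg = inside["class_label"].astype(str).str.startswith("DEG")
    is_seg = inside["class_label"] == "SEG"
    grouped = pd.DataFrame(
        {
            "n_genes": inside.groupby("tad_id").size(),
            "n_DEG": inside[is_deg].groupby("tad_id").size(),
            "n_SEG": inside[is_seg].groupby("tad_id").size(),
        }
    )
    out = tads.set_index("tad_id").join(grouped).fillna(0).reset_index()
    for col in ("n_genes", "n_DEG", "n_SEG"):
        out[col] = out[col].astype(int)
    out["length"] = out["end"] - out["start"]
    out["density"] = out["n_genes"] * 100_000 / out["length"]
    out["content"] = np.select(
        [
            (out["n_DEG"] > 0) & (out["n_SEG"] > 0),
            out["n_DEG"] > 0,
            out["n_SEG"] > 0,
        ],
        ["mixed", "DEG_only", "SEG_only"],
        default="neither",
    )
    return out[
        ["tad_id", "chrom", "start", "end", "length", "n_genes", "n_DEG", "n_SEG", "density", "content"]
    ]


def tad_cooccurrence_test(
    tads: pd.DataFrame,
    genes: pd.DataFrame,
    deg_ids,
    seg_ids,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Do DEGs and SEGs share TADs less often than chance?

    The statistic is the number of TADs containing at least one gene of each
    class; the null shuffles the class labels over the labelled genes'
    (fixed) positions. The reported p-value is left-tailed (observed mixing
    at or below the null), matching the segregation hypothesis.
    """
    deg_ids, seg_ids = set(deg_ids), set(seg_ids)
    labelled = genes[genes["gene_id"].isin(deg_ids | seg_ids)].copy()
    labelled["tad_id"] = assign_genes_to_tads(tads, labelled)
    labelled = labelled.dropna(subset=["tad_id"])
    labels = labelled["gene_id"].isin(deg_ids).to_numpy()  # True = DEG
    tad_codes, _ = pd.factorize(labelled["tad_id"])
    n_tads = tad_codes.max() + 1 if len(tad_codes) else 0

    counts = np.bincount(tad_codes, minlength=n_tads)
    if not (counts >= 2).any():
        logger.warning("no TAD contains >= 2 labelled genes; co-occurrence undefined")
        return {"report": None, "intersections": {}}

    def n_mixed(lab: np.ndarray) -> int:
        has_deg = np.bincount(tad_codes, weights=lab, minlength=n_tads) > 0
        has_seg = np.bincount(tad_codes, weights=~lab, minlength=n_tads) > 0
        return int(np.sum(has_deg & has_seg))

    observed = n_mixed(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    lab = labels.copy()
    for i in range(n_perm):
        rng.shuffle(lab)
        null[i] = n_mixed(lab)
    report = make_report("n_mixed_tads", observed, null, direction="le", seed=seed)
    has_deg = np.bincount(tad_codes, weights=labels, minlength=n_tads) > 0
    has_seg = np.bincount(tad_codes, weights=~labels, minlength=n_tads) > 0
    intersections = {
        "DEG_only": int(np.sum(has_deg & ~has_seg)),
        "SEG_only": int(np.sum(~has_deg & has_seg)),
        "mixed": observed,
        "null_mean_mixed": float(null.mean()),
    }
    return {"report": report, "intersections": intersections}


# --- CG-rich promoters ----------------------------------------------------

GC_MIN = 0.5          # Gardiner-Garden GC fraction
CPG_OE_MIN = 0.6      # Gardiner-Garden CpG observed/expected
MIN_PROMOTER_LEN = 200


def promoter_gc_stats(seq: str) -> dict:
    """GC fraction and CpG observed/expected ratio of a promoter sequence."""
    seq = seq.upper()
    n = len(seq)
    c = seq.count("C")
    g = seq.count("G")
    cpg = sum(1 for i in range(n - 1) if seq[i : i + 2] == "CG")
    gc_frac = (c + g) / n if n else 0.0
    oe = (cpg * n) / (c * g) if c and g else 0.0
    return {"length": n, "gc_frac": gc_frac, "cpg_oe": oe}


def cg_rich_promoter(
    stats_df: pd.DataFrame | None = None,
    sequences: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Classify promoters as CG-rich by CpG-island-style criteria.

    Input is either a stats table (gene_id, length, gc_frac, cpg_oe) or a
    gene_id -> promoter sequence mapping (stats computed here). CG-rich
    means GC fraction > 0.5 and CpG O/E > 0.6 over at least 200 bp.
    """
    if stats_df is None:
        if sequences is None:
            raise ValueError("provide per-promoter stats or sequences")
        stats_df = pd.DataFrame(
            [{"gene_id": g, **promoter_gc_stats(s)} for g, s in sequences.items()]
        )
    out = stats_df.copy()
    out["cg_rich"] = (
        (out["gc_frac"] > GC_MIN)
        & (out["cpg_oe"] > CPG_OE_MIN)
        & (out["length"] >= MIN_PROMOTER_LEN)
    )
    return out


def cg_rich_fisher(n_rich_a: int, n_a: int, n_rich_b: int, n_b: int) -> dict:
    """One-tailed Fisher test: is class A enriched for CG-rich promoters?"""
    table = [[n_rich_a, n_a - n_rich_a], [n_rich_b, n_b - n_rich_b]]
    odds, p = sps.fisher_exact(table, alternative="greater")
    return {"odds_ratio": float(odds), "p_value": float(p), "table": table}
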