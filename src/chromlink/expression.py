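"""Gene classification by the Berger-Parker dominance index.

A gene expressed across three germ layers is *differentially expressed*
(DEG) when one lineage dominates its expression, and *similarly expressed*
(SEG) when all three carry nearly equal shares. Dominance of a triple
``v = (v1, v2, v3)`` of non-negative linear-scale values is

    Dom(v) = max(v) / sum(v)  in [1/3, 1],

1/3 indicating perfect evenness and 1 single-lineage exclusivity. Input
expression is log2 RPKM and is linearised (``2**GE``) before the ratio:
ratios of log values are meaningless near zero, and linearisation keeps
Dom scale-free and reproduces 0.33 for an even triple.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import Config, LINEAGES
from .stats import PermutationReport, permutation_pvalue

logger = logging.getLogger("chromlink")

EXPR_COLS = [f"GE_{lin}" for lin in LINEAGES]

#: absolute tolerance for inclusive threshold comparisons, so log2/linear
#: round-trip error cannot flip an exact boundary case like Dom = 0.6
THRESHOLD_ATOL = 1e-9


def dominance_index(values) -> float:
    """Berger-Parker dominance of a vector of non-negative linear values.

    Returns ``max(v)/sum(v)``; NaN when the vector sums to zero (the caller
    must treat such genes/windows as undefined, not as classified).
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("dominance requires non-negative values")
    total = v.sum()
    if total == 0:
        return float("nan")
    return float(v.max() / total)


def dominance(matrix: np.ndarray) -> np.ndarray:
    """Row-wise dominance of an (n, k) matrix; NaN for all-zero rows."""
    m = np.asarray(matrix, dtype=float)
    if (m < 0).any():
        raise ValueError("dominance requires non-negative values")
    total = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = m.max(axis=1) / total
    out[total == 0] = np.nan
    return out


def linearize(expr: pd.DataFrame) -> np.ndarray:
    """log2 RPKM -> linear RPKM matrix over the canonical lineage order."""
    return np.exp2(expr[EXPR_COLS].to_numpy(dtype=float))


def classify_genes(
    expr: pd.DataFrame,
    config: Config | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign each gene a label: DEG of its dominant lineage, SEG, or unclassified.

    DEG_<lin>: Dom >= d_high (default 0.6) with the dominant lineage above
    the expression floor (log2 RPKM > 2 by default). SEG: Dom <= d_low
    (default 0.34) with all lineages expressed (log2 RPKM > 0). Everything
    between the thresholds, or failing a floor, is unclassified. Genes with
    undefined dominance (zero total linear expression) are excluded from the
    result and logged.

    Returns a DataFrame with gene_id, dom, lineage (argmax) and class_label.
    """
    cfg = config or Config()
    if annotation is not None:
        missing = set(expr["gene_id"]) - set(annotation["gene_id"])
        if missing:
            raise ValueError(f"genes absent from annotation: {sorted(missing)[:10]}")
    linear = linearize(expr)
    dom = dominance(linear)
    argmax = np.array(LINEAGES)[np.argmax(linear, axis=1)]
    log2 = expr[EXPR_COLS].to_numpy(dtype=float)
    dominant_ge = log2[np.arange(len(log2)), np.argmax(linear, axis=1)]

    label = np.full(len(expr), "unclassified", dtype=object)
    is_deg = (dom >= cfg.d_high - THRESHOLD_ATOL) & (dominant_ge > cfg.deg_min_expr)
    is_seg = (dom <= cfg.d_low + THRESHOLD_ATOL) & (log2 > cfg.seg_min_expr).all(axis=1)
    label[is_deg] = np.char.add("DEG_", argmax[is_deg].astype(str))
    label[is_seg] = "SEG"

    out = pd.DataFrame(
        {
            "gene_id": expr["gene_id"].to_numpy(),
            "dom": dom,
            "lineage": argmax,
            "class_label": label,
        }
    )
    undefined = np.isnan(dom)
    if undefined.any():
        logger.info("excluding %d genes with undefined dominance", int(undefined.sum()))
        out = out[~undefined].reset_index(drop=True)
    counts = out["class_label"].value_counts().to_dict()
    logger.info(
        "classified %d genes at d_high=%.2f d_low=%.2f: %s",
        len(out), cfg.d_high, cfg.d_low, counts,
    )
    return out


def mad_deg_strategy(
    expr: pd.DataFrame,
    fold: float = 3.0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Fold-change DEG calling with a robust (MAD-based) z-score filter.

    A gene is flagged for lineage L when its linear expression exceeds
    ``fold`` times each other lineage AND its log2 difference against each
    other lineage is an outlier of the gene-wise difference distribution:
    robust z = (d - median(d)) / (1.4826 * MAD(d)) above the two-sided
    ``alpha`` normal quantile. When a difference distribution has MAD = 0
    the filter falls back to percentile ranks with a warning.

    Returns per-gene boolean flags ``mad_<lin>``.
    """
    log2 = expr[EXPR_COLS].to_numpy(dtype=float)
    z_crit = sps.norm.ppf(1 - alpha / 2)
    flags = {}
    for i, lin in enumerate(LINEAGES):
        ok = np.ones(len(expr), dtype=bool)
        for j in range(3):
            if j == i:
                continue
            d = log2[:, i] - log2[:, j]
            med = np.median(d)
            mad = np.median(np.abs(d - med))
            if mad == 0:
                logger.warning(
                    "MAD = 0 for %s vs %s; falling back to rank-based flagging",
                    lin, LINEAGES[j],
                )
                ranks = sps.rankdata(d) / len(d)
                outlier = ranks > 1 - alpha / 2
            else:
                z = (d - med) / (1.4826 * mad)
                outlier = z > z_crit
            ok &= (d > np.log2(fold)) & outlier
        flags[f"mad_{lin}"] = ok
    return pd.DataFrame({"gene_id": expr["gene_id"].to_numpy(), **flags})


def jaccard_sets(a, b) -> float:
    """Jaccard similarity of two id sets; 1.0 when both are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def strategy_agreement(classes: pd.DataFrame, mad_flags: pd.DataFrame) -> float:
    """Jaccard between dominance-called DEGs and MAD-called DEGs (any lineage)."""
    dom_degs = set(classes.loc[classes["class_label"].str.startswith("DEG"), "gene_id"])
    mad_cols = [c for c in mad_flags.columns if c.startswith("mad_")]
    mad_degs = set(mad_flags.loc[mad_flags[mad_cols].any(axis=1), "gene_id"])
    return jaccard_sets(dom_degs, mad_degs)


def dominance_permutation_test(
    expr: pd.DataFrame,
    threshold: float,
    direction: str,
    n_perm: int = 1000,
    seed: int = 0,
    lineage: str | None = None,
    min_ge: float = 2.0,
    expressed_floor: float = 0.0,
) -> PermutationReport:
    """Permutation test of a dominance threshold's attainability by chance.

    Random expression triples are assembled by drawing one gene's value
    uniformly and independently within each lineage, from a pool of genes
    expressed in at least one lineage (SEG test; ``lineage=None``) or of
    genes with log2 RPKM > ``min_ge`` in the conditioning lineage (DEG
    test). The p-value is the fraction of permuted triples whose dominance
    satisfies ``direction`` ("le" or "ge") relative to ``threshold``, with
    the add-one convention (0 hits in n permutations reported as 1/n).
    """
    if direction not in ("le", "ge"):
        raise ValueError("direction must be 'le' or 'ge'")
    log2 = expr[EXPR_COLS].to_numpy(dtype=float)
    if lineage is None:
        pool = log2[(log2 > expressed_floor).any(axis=1)]
    else:
        if lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {lineage!r}")
        pool = log2[log2[:, LINEAGES.index(lineage)] > min_ge]
    if len(pool) < 10:
        raise ValueError(f"permutation pool too small ({len(pool)} genes)")
    rng = np.random.default_rng(seed)
    linear = np.exp2(pool)
    idx = rng.integers(0, len(pool), size=(n_perm, 3))
    triples = linear[idx, np.arange(3)]
    dom = dominance(triples)
    if direction == "le":
        k = int(np.sum(dom <= threshold))
    else:
        k = int(np.sum(dom >= threshold))
    return PermutationReport(
        statistic=f"Dom {'<=' if direction == 'le' else '>='} {threshold}",
        observed=threshold,
        n_perm=n_perm,
        n_exceeding=k,
        p_value=permutation_pvalue(k, n_perm),
        seed=seed,
    )
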