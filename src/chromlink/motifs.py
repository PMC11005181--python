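"""Comparing transcription-factor motif repertoires across region sets.

Eight regulatory-region sets (per-lineage putative enhancers and core
promoters of differentially expressed genes, plus one enhancer and one
promoter set for similarly expressed genes) each come with a ranked list of
enriched TF binding motifs. Every list is encoded over the union of all
motifs as a quartile-rank vector: 1 for the top enrichment quartile of the
list through 4 for the bottom quartile, 0 for motifs absent from the list.
Repertoire similarity between two sets is the RMSE between their vectors
(distance from the y = x line; higher RMSE = less similar), compared
within vs between the developmental and housekeeping groups, with a
GC-stratified permutation null since housekeeping-associated motifs are
systematically GC-richer.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import PermutationReport, make_report

logger = logging.getLogger("chromlink")

#: fractional nucleotide composition of IUPAC degenerate symbols
IUPAC = {
    "A": {"A": 1.0}, "C": {"C": 1.0}, "G": {"G": 1.0}, "T": {"T": 1.0},
    "R": {"A": 0.5, "G": 0.5}, "Y": {"C": 0.5, "T": 0.5},
    "S": {"C": 0.5, "G": 0.5}, "W": {"A": 0.5, "T": 0.5},
    "K": {"G": 0.5, "T": 0.5}, "M": {"A": 0.5, "C": 0.5},
    "B": {"C": 1 / 3, "G": 1 / 3, "T": 1 / 3},
    "D": {"A": 1 / 3, "G": 1 / 3, "T": 1 / 3},
    "H": {"A": 1 / 3, "C": 1 / 3, "T": 1 / 3},
    "V": {"A": 1 / 3, "C": 1 / 3, "G": 1 / 3},
    "N": {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
}
NUCS = ("A", "C", "G", "T")
DINUCS = tuple(a + b for a in NUCS for b in NUCS)


def filter_by_expression(
    entries: pd.DataFrame,
    expr: pd.DataFrame,
    classes: pd.DataFrame | None = None,
    min_ge: float = 0.0,
) -> pd.DataFrame:
    """Drop motifs whose origin TF gene is not expressed; annotate origin class.

    A motif is kept when its origin gene has log2 RPKM > ``min_ge`` in at
    least one lineage. Origin class (DEG_<lin> / SEG / other) comes from the
    gene classification when provided. Motifs with unresolvable origin
    genes are dropped and logged.
    """
    ge_cols = [c for c in expr.columns if c.startswith("GE_")]
    expr_idx = expr.set_index("gene_id")
    out = entries.copy()
    resolvable = out["origin_gene"].isin(expr_idx.index)
    if (~resolvable).any():
        logger.info("dropping %d motifs with unresolvable origin genes", int((~resolvable).sum()))
    out = out[resolvable].copy()
    ge = expr_idx.loc[out["origin_gene"], ge_cols].to_numpy(dtype=float)
    expressed = (ge > min_ge).any(axis=1)
    out = out[expressed].copy()
    if classes is not None:
        label = classes.set_index("gene_id")["class_label"]
        origin = out["origin_gene"].map(label).fillna("other")
        origin = origin.where(origin.isin({"SEG"}) | origin.str.startswith("DEG"), "other")
        out["origin_class"] = origin.to_numpy()
    logger.info("expression filter kept %d / %d motifs", len(out), len(entries))
    return out.reset_index(drop=True)


def quartile_ranks(n: int) -> np.ndarray:
    """Quartile labels 1..4 for 1-based ranks of an n-item list.

    Boundaries use the ceiling partition: ranks up to ceil(n/4) are quartile
    1, up to ceil(n/2) quartile 2, up to ceil(3n/4) quartile 3, rest 4
    (a 5-item list splits 2,1,1,1).
    """
    ranks = np.arange(1, n + 1)
    bounds = [int(np.ceil(n * q / 4)) for q in (1, 2, 3)]
    return np.select(
        [ranks <= bounds[0], ranks <= bounds[1], ranks <= bounds[2]],
        [1, 2, 3],
        default=4,
    )


def build_vector(entries: pd.DataFrame, union: list[str]) -> np.ndarray:
    """Quartile-rank feature vector of one motif list over the shared union.

    Entries are ordered by enrichment score descending (most significant
    first); each motif gets its list quartile 1-4, and union motifs absent
    from the list get 0.
    """
    ordered = entries.sort_values("score", ascending=False, kind="mergesort")
    ranks = quartile_ranks(len(ordered))
    by_motif = dict(zip(ordered["motif"], ranks))
    unknown = set(ordered["motif"]) - set(union)
    if unknown:
        raise ValueError(f"motifs outside the union: {sorted(unknown)[:5]}")
    return np.array([by_motif.get(m, 0) for m in union], dtype=float)


def build_vectors(lists: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, list[str]]:
    """Feature vectors for all region sets over their motif union."""
    union = sorted(set(itertools.chain.from_iterable(df["motif"] for df in lists.values())))
    mat = pd.DataFrame(
        {name: build_vector(df, union) for name, df in lists.items()},
        index=union,
    )
    return mat, union


def rmse_similarity(v1, v2) -> float:
    """RMSE between two equal-length rank vectors (0 = identical repertoires)."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must share the motif union")
    return float(np.sqrt(np.mean((v1 - v2) ** 2)))


def pairwise_rmse(vectors: pd.DataFrame) -> pd.DataFrame:
    """Symmetric RMSE matrix across all vector columns."""
    names = list(vectors.columns)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        d = rmse_similarity(vectors[a], vectors[b])
        out.loc[a, b] = out.loc[b, a] = d
    return out


def _group_gap(vectors: pd.DataFrame, groups: dict[str, str]) -> tuple[float, dict]:
    """Between-group minus within-group median pairwise RMSE (positive = structure)."""
    within, between = [], []
    cells: dict[tuple[str, str], list[float]] = {}
    for a, b in itertools.combinations(vectors.columns, 2):
        d = rmse_similarity(vectors[a], vectors[b])
        ga, gb = groups[a], groups[b]
        key = tuple(sorted((ga, gb)))
        cells.setdefault(key, []).append(d)
        (within if ga == gb else between).append(d)
    table = {f"{a}~{b}": float(np.median(v)) for (a, b), v in cells.items()}
    if not within or not between:
        return float("nan"), {"medians": table, "within": within, "between": between}
    gap = float(np.median(between) - np.median(within))
    return gap, {"medians": table, "within": within, "between": between}


def group_similarity(
    vectors: pd.DataFrame,
    groups: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Within- vs between-group repertoire similarity.

    ``groups`` maps each vector column to its group (e.g. DEG_enhancer,
    SEG_promoter). Reports the median pairwise RMSE per group pair, a
    Welch t-test on within vs between pairwise values, and a label-
    permutation test on the between-minus-within median gap.
    """
    gap, detail = _group_gap(vectors, groups)
    within, between = detail["within"], detail["between"]
    if within and between and (np.std(within) > 0 or np.std(between) > 0):
        t_stat, t_p = sps.ttest_ind(between, within, equal_var=False)
    else:
        t_stat, t_p = float("nan"), 1.0
    rng = np.random.default_rng(seed)
    names = list(vectors.columns)
    labels = [groups[n] for n in names]
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = list(rng.permutation(labels))
        null[i] = _group_gap(vectors, dict(zip(names, perm)))[0]
    report = make_report("between_minus_within_median_rmse", gap, null, direction="ge", seed=seed)
    return {
        "medians": detail["medians"],
        "gap": gap,
        "t_statistic": float(t_stat),
        "t_p_value": float(t_p),
        "report": report,
    }


def consensus_gc(consensus: str) -> float:
    """GC content of a consensus with fractional IUPAC resolution."""
    probs = [IUPAC[ch] for ch in consensus.upper()]
    return float(np.mean([p.get("C", 0) + p.get("G", 0) for p in probs]))


def gc_stratified_permutation(
    vectors: pd.DataFrame,
    groups: dict[str, str],
    gc_content: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    n_strata: int = 4,
) -> PermutationReport:
    """Group-structure test with a GC-preserving null.

    Motifs (rows of the vector matrix) are stratified into quartiles of
    their consensus GC content; each permutation shuffles every vector's
    entries among the motifs of a stratum, preserving each repertoire's
    rank multiset per GC class. The statistic is the between-minus-within
    median RMSE gap. Strata of size 1 make the permutation the identity.
    """
    gc = gc_content.reindex(vectors.index)
    if gc.isna().any():
        raise ValueError("GC content missing for some union motifs")
    # quartile strata; duplicate edges collapse for skewed GC distributions
    try:
        strata = pd.qcut(gc, n_strata, labels=False, duplicates="drop")
    except ValueError:
        strata = pd.Series(0, index=gc.index)
    observed, _ = _group_gap(vectors, groups)
    rng = np.random.default_rng(seed)
    values = vectors.to_numpy()
    idx_by_stratum = [
        np.flatnonzero(strata.to_numpy() == s) for s in np.unique(strata.dropna())
    ]
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_vals = values.copy()
        for col in range(values.shape[1]):
            for idx in idx_by_stratum:
                perm_vals[idx, col] = values[rng.permutation(idx), col]
        perm_df = pd.DataFrame(perm_vals, index=vectors.index, columns=vectors.columns)
        null[i], _ = _group_gap(perm_df, groups)
    return make_report("gc_stratified_gap", observed, null, direction="ge", seed=seed)


# --- motif sequence features ----------------------------------------------

@dataclass
class MotifFeatures:
    """Sequence features of one motif consensus."""

    motif: str
    length: int
    px: dict
    pxy: dict
    entropy: float

    def to_dict(self) -> dict:
        return asdict(self)


def motif_features_one(motif: str, consensus: str) -> MotifFeatures:
    """Nucleotide content, dinucleotide content and dinucleotide entropy.

    Px = count(x)/length and Pxy = count(xy)/(length-1), with IUPAC
    degenerate symbols contributing fractionally; the entropy is
    -sum Pxy log2 Pxy over the 16 adjacent pairs (0 for homopolymers,
    at most 4 bits).
    """
    seq = consensus.upper()
    if any(ch not in IUPAC for ch in seq):
        raise ValueError(f"invalid consensus symbol in {consensus!r}")
    n = len(seq)
    probs = [IUPAC[ch] for ch in seq]
    px = {nuc: sum(p.get(nuc, 0.0) for p in probs) / n for nuc in NUCS}
    pxy = dict.fromkeys(DINUCS, 0.0)
    if n >= 2:
        for left, right in zip(probs, probs[1:]):
            for a, pa in left.items():
                for b, pb in right.items():
                    pxy[a + b] += pa * pb / (n - 1)
    vals = np.array([v for v in pxy.values() if v > 0])
    entropy = float(-(vals * np.log2(vals)).sum()) if len(vals) else 0.0
    return MotifFeatures(motif=motif, length=n, px=px, pxy=pxy, entropy=entropy)


def motif_features(entries: pd.DataFrame) -> pd.DataFrame:
    """Feature table (length, Pa..Pt, entropy) for a motif list."""
    rows = []
    for row in entries.itertuples():
        f = motif_features_one(row.motif, row.consensus)
        rows.append(
            {
                "motif": f.motif,
                "length": f.length,
                **{f"P{n.lower()}": f.px[n] for n in NUCS},
                "entropy": f.entropy,
            }
        )
    return pd.DataFrame(rows)


def high_ranked(entries: pd.DataFrame) -> set[str]:
    """Motifs in the top enrichment quartile of one list."""
    ordered = entries.sort_values("score", ascending=False, kind="mergesort")
    q = quartile_ranks(len(ordered))
    return set(ordered["motif"].to_numpy()[q == 1])


def signature_motifs(lists: dict[str, pd.DataFrame]) -> dict[str, set[str]]:
    """Developmental vs housekeeping signature motif sets.

    The housekeeping (SEG) signature is the intersection of high-ranked
    motifs between the SEG enhancer and SEG promoter lists; the
    developmental (DEG) signature is the union over lineages of the
    per-lineage enhancer/promoter high-rank intersections.
    """
    deg: set[str] = set()
    for lin in ("ect", "end", "mes"):
        enh = lists.get(f"DEG_{lin}_enhancer")
        pro = lists.get(f"DEG_{lin}_promoter")
        if enh is not None and pro is not None:
            deg |= high_ranked(enh) & high_ranked(pro)
    seg: set[str] = set()
    enh, pro = lists.get("SEG_enhancer"), lists.get("SEG_promoter")
    if enh is not None and pro is not None:
        seg = high_ranked(enh) & high_ranked(pro)
    return {"DEG": deg, "SEG": seg}


def compare_feature_groups(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    columns=("entropy", "Pa", "length"),
) -> pd.DataFrame:
    """Nonparametric comparison of motif features between two signature sets.

    Mann-Whitney (two-sided) and Kruskal-Wallis per feature; both reduce to
    the same comparison for two groups but the H statistic is reported for
    parity with multi-group use.
    """
    rows = []
    for col in columns:
        a = features_a[col].to_numpy(dtype=float)
        b = features_b[col].to_numpy(dtype=float)
        mw = sps.mannwhitneyu(a, b, alternative="two-sided")
        kw = sps.kruskal(a, b)
        rows.append(
            {
                "feature": col,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "mannwhitney_p": float(mw.pvalue),
                "kruskal_p": float(kw.pvalue),
            }
        )
    return pd.DataFrame(rows)
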