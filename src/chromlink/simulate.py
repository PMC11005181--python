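"""Synthetic multi-omic dataset generator with planted ground truth.

Emulates the statistical structure of a three-germ-layer gastrulation
pseudo-bulk dataset so every downstream stage is testable without
downloads: log-normal expression with planted lineage-dominant (DEG) and
even (SEG) genes; SEGs packed into dense gene clusters inside SEG-rich
TADs while DEGs sit isolated in their own TADs; accessibility windows with
Poisson coverage, open regions planted distally (within +/-100 kB) around
DEGs at counts proportional to expression and proximally at SEG promoters;
methylation windows anti-correlated with accessibility (hypomethylated
where open); and eight enriched-motif lists drawn from two grammars with
controlled overlap and GC composition.

Identical spec + seed gives byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import LINEAGES
from .io import window_columns, write_regions_bed

logger = logging.getLogger("chromlink")


@dataclass
class SimulationSpec:
    """Parameters of the planted dataset; defaults are the study conditions.

    Expression is Normal in log2 RPKM space (heavy-tailed in linear RPKM).
    A planted DEG carries its dominant lineage at ``deg_off_mu + deg_delta``
    log2 RPKM (a 16-fold linear boost by default) over two lowly expressed
    off-lineages. A planted SEG shares one well-expressed baseline across
    lineages with very small within-gene noise, because the evenness
    criterion Dom <= 0.34 tolerates only a few percent of linear
    imbalance. Background genes share a baseline with moderate
    lineage noise, as real transcriptomes are lineage-correlated.
    """

    seed: int = 0
    n_chrom: int = 3
    chrom_length: int = 16_000_000
    n_genes: int = 300
    frac_deg: float = 0.30          # split evenly over the three lineages
    frac_seg: float = 0.30

    # expression model (log2 RPKM)
    expr_mu: float = 4.0
    expr_sigma: float = 2.5
    deg_delta: float = 4.0          # dominant-lineage log2 boost
    deg_off_mu: float = 1.0
    deg_off_sigma: float = 0.8
    seg_base_sigma: float = 1.5
    seg_noise: float = 0.01         # within-gene lineage s.d. for SEGs
    bg_noise: float = 0.5           # within-gene lineage s.d. for background

    # placement model
    tad_deg_len: int = 400_000      # one isolated DEG per such TAD
    tad_seg_len: int = 300_000      # dense gene cluster per such TAD
    tad_gap: int = 10_000
    cluster_size: int = 8
    cluster_gap: float = 5_000.0    # mean inter-TSS gap inside clusters (bp)

    # accessibility model
    zone_length: int = 100_000      # planted distal zone half-width L
    dar_lam: float = 2.0            # DAR count per DEG ~ Poisson(lam * GE decile)
    sar_lam: float = 3.0            # SARs per SEG within +/- proximal_zone
    proximal_zone: int = 2_000
    n_background_windows: int = 1_000
    acc_window: int = 100
    mu_cov: float = 50.0            # reads per window per lineage
    mu_gc: float = 12.0             # GC dinucleotides per 100-bp window
    p_open: float = 0.75            # GpC methylation (= openness) when open
    p_closed: float = 0.08
    p_sar_open: float = 0.5
    p_background: float = 0.15

    # methylation model (500-bp windows)
    meth_window: int = 500
    mu_cg: float = 25.0
    p_hypo: float = 0.15
    p_meth: float = 0.85
    dhmr_frac: float = 0.5          # fraction of planted DARs with a matching DhMR
    n_background_meth: int = 500
    p_meth_background: float = 0.75

    # motif model
    n_motifs_per_list: int = 40
    motif_overlap: float = 0.2      # DEG-vs-SEG grammar sharing
    gc_split: float = 0.9           # P(GC-rich consensus) for SEG-grammar motifs
    frac_nonexpressed_origin: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.frac_deg + self.frac_seg <= 1:
            raise ValueError("class fractions must sum to at most 1")
        for name in ("dar_lam", "sar_lam", "mu_cov", "mu_gc", "mu_cg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted labels: per-gene class, per-region class and target, zone length."""

    gene_class: dict
    regions: pd.DataFrame
    zone_length: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_class": self.gene_class,
            "zone_length": self.zone_length,
            "regions": self.regions.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            gene_class=payload["gene_class"],
            regions=pd.DataFrame(payload["regions"]),
            zone_length=payload["zone_length"],
        )


# --------------------------------------------------------------------------

def _plan_classes(spec: SimulationSpec, rng: np.random.Generator) -> list[str]:
    n_deg = int(round(spec.n_genes * spec.frac_deg))
    n_seg = int(round(spec.n_genes * spec.frac_seg))
    per_lin = n_deg // 3
    classes = (
        [f"DEG_{lin}" for lin in LINEAGES for _ in range(per_lin)]
        + ["DEG_" + LINEAGES[i % 3] for i in range(n_deg - 3 * per_lin)]
        + ["SEG"] * n_seg
        + ["background"] * (spec.n_genes - n_deg - n_seg)
    )
    return classes


def _place_genes(
    spec: SimulationSpec, classes: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out alternating DEG-poor / SEG-dense TADs and place genes in them."""
    deg_idx = [i for i, c in enumerate(classes) if c.startswith("DEG")]
    dense_idx = [i for i, c in enumerate(classes) if not c.startswith("DEG")]
    rng.shuffle(deg_idx)
    rng.shuffle(dense_idx)
    deg_queue = list(deg_idx)
    dense_queue = list(dense_idx)

    gene_rows, tad_rows = [], []
    tad_n = 0
    for chrom_i in range(spec.n_chrom):
        chrom = f"chr{chrom_i + 1}"
        pos = spec.tad_gap
        want_deg = True
        while deg_queue or dense_queue:
            if want_deg and deg_queue:
                length = spec.tad_deg_len
            elif dense_queue:
                length = spec.tad_seg_len
            elif deg_queue:
                length, want_deg = spec.tad_deg_len, True
            else:
                break
            if pos + length + spec.tad_gap > spec.chrom_length:
                break
            if want_deg and deg_queue:
                gi = deg_queue.pop()
                tss = pos + length // 2
                gene_rows.append((gi, chrom, tss))
            else:
                tss = pos + 50_000
                for _ in range(spec.cluster_size):
                    if not dense_queue or tss >= pos + length - 10_000:
                        break
                    gi = dense_queue.pop()
                    gene_rows.append((gi, chrom, tss))
                    tss += max(200, int(rng.exponential(spec.cluster_gap)))
            tad_rows.append((f"tad_{tad_n:05d}", chrom, pos, pos + length))
            tad_n += 1
            pos += length + spec.tad_gap
            want_deg = not want_deg
        if not deg_queue and not dense_queue:
            break
    if deg_queue or dense_queue:
        raise ValueError(
            f"{len(deg_queue) + len(dense_queue)} genes cannot fit the "
            f"configured chromosome length"
        )
    strands = rng.choice(["+", "-"], size=len(gene_rows))
    genes = pd.DataFrame(
        [
            {
                "gene_id": f"gene_{gi:05d}",
                "chrom": chrom,
                "strand": strands[k],
                "tss": tss,
                "true_class": classes[gi],
            }
            for k, (gi, chrom, tss) in enumerate(gene_rows)
        ]
    ).sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)
    tads = pd.DataFrame(tad_rows, columns=["tad_id", "chrom", "start", "end"])
    return genes, tads


def _simulate_expression(
    spec: SimulationSpec, genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for row in genes.itertuples():
        cls = row.true_class
        if cls.startswith("DEG"):
            lin = cls.split("_")[1]
            ge = rng.normal(spec.deg_off_mu, spec.deg_off_sigma, size=3)
            ge[LINEAGES.index(lin)] = rng.normal(
                spec.deg_off_mu + spec.deg_delta, spec.deg_off_sigma
            )
        elif cls == "SEG":
            base = max(0.5, rng.normal(spec.expr_mu, spec.seg_base_sigma))
            ge = base + rng.normal(0.0, spec.seg_noise, size=3)
        else:
            base = rng.normal(spec.expr_mu, spec.expr_sigma)
            ge = base + rng.normal(0.0, spec.bg_noise, size=3)
        rows.append((row.gene_id, *ge))
    return pd.DataFrame(rows, columns=["gene_id", "GE_ect", "GE_end", "GE_mes"])


def _snap(pos: np.ndarray, width: int) -> np.ndarray:
    return (np.asarray(pos, dtype=np.int64) // width) * width


def _window_counts(
    spec: SimulationSpec,
    p_by_lin: np.ndarray,
    rng: np.random.Generator,
    mu_total: float,
) -> list:
    """Per-lineage (reads, total, meth) triple for one window."""
    out = []
    for p in p_by_lin:
        reads = int(rng.poisson(spec.mu_cov))
        total = max(1, int(rng.poisson(mu_total)))
        meth = int(rng.binomial(total, p))
        out += [reads, total, meth]
    return out


def _ge_deciles(values: np.ndarray) -> np.ndarray:
    """1..10 decile of each value within the vector (1 = lowest)."""
    order = np.argsort(np.argsort(values))
    return 1 + (order * 10) // len(values)


def _simulate_accessibility(
    spec: SimulationSpec,
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window count table plus the planted-region truth records."""
    merged = genes.merge(expr, on="gene_id")
    lin_idx = {lin: i for i, lin in enumerate(LINEAGES)}
    windows, truth = [], []

    degs = merged[merged["true_class"].str.startswith("DEG")].copy()
    dom_ge = np.array(
        [
            getattr(r, f"GE_{r.true_class.split('_')[1]}")
            for r in degs.itertuples()
        ]
    )
    deciles = _ge_deciles(dom_ge) if len(degs) else np.array([], dtype=int)
    for (row, dec) in zip(degs.itertuples(), deciles):
        lin = row.true_class.split("_")[1]
        n_dar = rng.poisson(spec.dar_lam * dec)
        lo = max(0, row.tss - spec.zone_length)
        hi = row.tss + spec.zone_length
        starts = _snap(rng.integers(lo, hi, size=n_dar), spec.acc_window)
        p = np.full(3, spec.p_closed)
        p[lin_idx[lin]] = spec.p_open
        for s in starts:
            windows.append((row.chrom, int(s), int(s) + spec.acc_window,
                            *_window_counts(spec, p, rng, spec.mu_gc)))
            truth.append((row.chrom, int(s), int(s) + spec.acc_window,
                          "DAR", lin, row.gene_id))

    segs = merged[merged["true_class"] == "SEG"]
    for row in segs.itertuples():
        n_sar = rng.poisson(spec.sar_lam)
        lo = max(0, row.tss - spec.proximal_zone)
        hi = row.tss + spec.proximal_zone
        starts = _snap(rng.integers(lo, hi, size=n_sar), spec.acc_window)
        p = np.full(3, spec.p_sar_open)
        for s in starts:
            windows.append((row.chrom, int(s), int(s) + spec.acc_window,
                            *_window_counts(spec, p, rng, spec.mu_gc)))
            truth.append((row.chrom, int(s), int(s) + spec.acc_window,
                          "SAR", "all", row.gene_id))

    chroms = [f"chr{i + 1}" for i in range(spec.n_chrom)]
    for _ in range(spec.n_background_windows):
        chrom = chroms[rng.integers(0, len(chroms))]
        s = int(_snap(rng.integers(0, spec.chrom_length), spec.acc_window))
        p = np.full(3, spec.p_background)
        windows.append((chrom, s, s + spec.acc_window,
                        *_window_counts(spec, p, rng, spec.mu_gc)))

    df = pd.DataFrame(windows, columns=window_columns())
    df = df.drop_duplicates(subset=["chrom", "start"], keep="first")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    truth_df = pd.DataFrame(
        truth, columns=["chrom", "start", "end", "kind", "lineage", "target_gene"]
    ).drop_duplicates(subset=["chrom", "start", "kind"], keep="first")
    return df, truth_df


def _simulate_methylation(
    spec: SimulationSpec,
    genes: pd.DataFrame,
    acc_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """500-bp CpG windows anti-correlated with accessibility at planted sites."""
    lin_idx = {lin: i for i, lin in enumerate(LINEAGES)}
    windows, truth = [], []

    dars = acc_truth[acc_truth["kind"] == "DAR"]
    pick = rng.random(len(dars)) < spec.dhmr_frac
    for row, keep in zip(dars.itertuples(), pick):
        if not keep:
            continue
        s = int(_snap([row.start], spec.meth_window)[0])
        p = np.full(3, spec.p_meth)
        p[lin_idx[row.lineage]] = spec.p_hypo
        windows.append((row.chrom, s, s + spec.meth_window,
                        *_window_counts(spec, p, rng, spec.mu_cg)))
        truth.append((row.chrom, s, s + spec.meth_window, "DhMR", row.lineage,
                      row.target_gene))

    segs = genes[genes["true_class"] == "SEG"]
    for row in segs.itertuples():
        s = int(_snap([max(0, row.tss - spec.meth_window // 2)], spec.meth_window)[0])
        p = np.full(3, spec.p_hypo)
        windows.append((row.chrom, s, s + spec.meth_window,
                        *_window_counts(spec, p, rng, spec.mu_cg)))
        truth.append((row.chrom, s, s + spec.meth_window, "ShMR", "all", row.gene_id))

    chroms = [f"chr{i + 1}" for i in range(spec.n_chrom)]
    for _ in range(spec.n_background_meth):
        chrom = chroms[rng.integers(0, len(chroms))]
        s = int(_snap([rng.integers(0, spec.chrom_length)], spec.meth_window)[0])
        p = np.full(3, spec.p_meth_background)
        windows.append((chrom, s, s + spec.meth_window,
                        *_window_counts(spec, p, rng, spec.mu_cg)))

    df = pd.DataFrame(windows, columns=window_columns())
    df = df.drop_duplicates(subset=["chrom", "start"], keep="first")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    truth_df = pd.DataFrame(
        truth, columns=["chrom", "start", "end", "kind", "lineage", "target_gene"]
    ).drop_duplicates(subset=["chrom", "start", "kind"], keep="first")
    return df, truth_df


# --- motif lists ----------------------------------------------------------

def _random_consensus(rng: np.random.Generator, gc_rich: bool) -> str:
    length = int(rng.integers(6, 13))
    p_gc = 0.75 if gc_rich else 0.25
    probs = [p_gc / 2, p_gc / 2, (1 - p_gc) / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(["G", "C", "A", "T"], size=length, p=probs))


LIST_NAMES = (
    "DEG_ect_enhancer", "DEG_end_enhancer", "DEG_mes_enhancer",
    "DEG_ect_promoter", "DEG_end_promoter", "DEG_mes_promoter",
    "SEG_enhancer", "SEG_promoter",
)


def generate_motif_lists(
    n_motifs: int = 40,
    overlap_fraction: float = 0.2,
    gc_split: float = 0.9,
    seed: int = 0,
    origin_genes: dict[str, list[str]] | None = None,
    frac_nonexpressed: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Eight enriched-motif lists drawn from two grammars.

    A developmental and a housekeeping grammar share ``overlap_fraction``
    of their motifs; each list samples ``n_motifs`` motifs from its
    grammar, so lists within a group overlap heavily and lists across
    groups overlap at roughly the grammar-sharing rate. Housekeeping-
    grammar consensi are GC-rich with probability ``gc_split``,
    developmental ones with probability ``1 - gc_split``. Scores are
    -log10 enrichment p-values, descending within each list. Origin genes
    are drawn from ``origin_genes['DEG_<lin>']`` / ``['SEG']`` pools when
    given (otherwise synthesised), with ``frac_nonexpressed`` of motifs
    deliberately assigned a non-expressed origin.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    grammar_size = max(n_motifs, int(round(n_motifs * 1.25)))
    n_shared = int(round(overlap_fraction * grammar_size))
    if n_shared > grammar_size:
        raise ValueError("overlap_fraction infeasible for the grammar size")
    n_total = 2 * grammar_size - n_shared
    names = [f"M{i:04d}" for i in range(n_total)]
    deg_grammar = names[:grammar_size]
    seg_grammar = names[grammar_size - n_shared:]

    gc_rich = {}
    for m in names:
        in_seg = m in seg_grammar
        in_deg = m in deg_grammar
        if in_seg and in_deg:
            p = 0.5
        elif in_seg:
            p = gc_split
        else:
            p = 1 - gc_split
        gc_rich[m] = bool(rng.random() < p)
    consensus = {m: _random_consensus(rng, gc_rich[m]) for m in names}

    origin: dict[str, str] = {}
    nonexpressed = set(
        rng.choice(names, size=int(round(frac_nonexpressed * n_total)), replace=False)
    )
    for m in names:
        if m in nonexpressed:
            origin[m] = f"tf_off_{m}"
            continue
        pool_key = "SEG" if m in seg_grammar and m not in deg_grammar else None
        if pool_key is None:
            lin = LINEAGES[int(rng.integers(0, 3))]
            pool_key = f"DEG_{lin}"
        if origin_genes and origin_genes.get(pool_key):
            pool = origin_genes[pool_key]
            origin[m] = pool[int(rng.integers(0, len(pool)))]
        else:
            origin[m] = f"tf_{m}"

    lists = {}
    for list_name in LIST_NAMES:
        grammar = seg_grammar if list_name.startswith("SEG") else deg_grammar
        if n_motifs > len(grammar):
            raise ValueError("n_motifs exceeds grammar size")
        chosen = rng.choice(grammar, size=n_motifs, replace=False)
        scores = np.sort(3.0 + rng.exponential(2.0, size=n_motifs))[::-1]
        lists[list_name] = pd.DataFrame(
            {
                "motif": chosen,
                "score": np.round(scores, 4),
                "consensus": [consensus[m] for m in chosen],
                "origin_gene": [origin[m] for m in chosen],
            }
        )
    return lists


# --- top level ------------------------------------------------------------

def generate_dataset(spec: SimulationSpec | None = None) -> dict:
    """Generate the full synthetic dataset.

    Returns a dict with annotation, expression, acc_windows, meth_windows,
    tads, motif_lists and a :class:`GroundTruth`; all tables are in the
    exact formats the readers in :mod:`chromlink.io` accept.
    """
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    classes = _plan_classes(spec, rng)
    genes, tads = _place_genes(spec, classes, rng)
    expr = _simulate_expression(spec, genes, rng)
    acc_windows, acc_truth = _simulate_accessibility(spec, genes, expr, rng)
    meth_windows, meth_truth = _simulate_methylation(spec, genes, acc_truth, rng)

    origin_pools: dict[str, list[str]] = {}
    for lin in LINEAGES:
        origin_pools[f"DEG_{lin}"] = list(
            genes.loc[genes["true_class"] == f"DEG_{lin}", "gene_id"]
        )
    origin_pools["SEG"] = list(genes.loc[genes["true_class"] == "SEG", "gene_id"])
    motif_lists = generate_motif_lists(
        n_motifs=spec.n_motifs_per_list,
        overlap_fraction=spec.motif_overlap,
        gc_split=spec.gc_split,
        seed=spec.seed + 1,
        origin_genes=origin_pools,
        frac_nonexpressed=spec.frac_nonexpressed_origin,
    )
    # non-expressed TF origins must exist in the expression table, silent
    off_genes = sorted(
        {
            g
            for df in motif_lists.values()
            for g in df["origin_gene"]
            if g.startswith("tf_")
        }
    )
    if off_genes:
        chrom = f"chr{spec.n_chrom}"
        extra_ann = pd.DataFrame(
            {
                "gene_id": off_genes,
                "chrom": chrom,
                "strand": "+",
                "tss": [
                    spec.chrom_length - 1_000_000 + 1_000 * i
                    for i in range(len(off_genes))
                ],
                "true_class": "background",
            }
        )
        extra_expr = pd.DataFrame(
            {
                "gene_id": off_genes,
                "GE_ect": -2.0,
                "GE_end": -2.0,
                "GE_mes": -2.0,
            }
        )
        genes = pd.concat([genes, extra_ann], ignore_index=True)
        expr = pd.concat([expr, extra_expr], ignore_index=True)

    truth = GroundTruth(
        gene_class=dict(zip(genes["gene_id"], genes["true_class"])),
        regions=pd.concat([acc_truth, meth_truth], ignore_index=True),
        zone_length=spec.zone_length,
    )
    annotation = genes[["gene_id", "chrom", "strand", "tss"]].copy()
    logger.info(
        "generated %d genes, %d TADs, %d acc windows, %d meth windows",
        len(annotation), len(tads), len(acc_windows), len(meth_windows),
    )
    return {
        "annotation": annotation,
        "expression": expr,
        "acc_windows": acc_windows,
        "meth_windows": meth_windows,
        "tads": tads,
        "motif_lists": motif_lists,
        "truth": truth,
        "spec": spec,
    }


def write_dataset(dataset: dict, out_dir: str | Path) -> None:
    """Write a generated dataset in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset["annotation"].to_csv(out / "annotation.tsv", sep="\t", index=False)
    dataset["expression"].to_csv(out / "expression.tsv", sep="\t", index=False)
    dataset["acc_windows"].to_csv(out / "acc_windows.tsv", sep="\t", index=False)
    dataset["meth_windows"].to_csv(out / "meth_windows.tsv", sep="\t", index=False)
    dataset["tads"][["chrom", "start", "end", "tad_id"]].to_csv(
        out / "tads.bed", sep="\t", index=False, header=False
    )
    motif_dir = out / "motifs"
    motif_dir.mkdir(exist_ok=True)
    for name, df in dataset["motif_lists"].items():
        df.to_csv(motif_dir / f"{name}.tsv", sep="\t", index=False)
    dataset["truth"].to_json(out / "truth.json")
    with open(out / "spec.json", "w") as fh:
        json.dump(asdict(dataset["spec"]), fh, indent=1)


# --- CAC benchmark --------------------------------------------------------

def simulate_cac_benchmark(
    seed: int = 0,
    n_genes: int = 300,
    chrom_length: int = 50_000_000,
    zone_length: int = 100_000,
    lam: float = 5.0,
    n_background: int = 300,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Planted zone-of-influence benchmark on one synthetic chromosome.

    ``n_genes`` lineage-dominant genes are placed uniformly; each gets
    Poisson(lam * GE decile) open regions uniformly within +/-zone_length
    of its TSS, plus ``n_background`` uniform background regions. Returns
    (genes with a ``ge`` column, regions) ready for the zone scan.
    """
    rng = np.random.default_rng(seed)
    tss = np.sort(rng.integers(zone_length, chrom_length - zone_length, size=n_genes))
    ge = rng.normal(4.0, 2.5, size=n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "chrom": "chr1",
            "strand": "+",
            "tss": tss,
            "ge": ge,
        }
    )
    deciles = _ge_deciles(ge)
    starts = []
    for pos, dec in zip(tss, deciles):
        n = rng.poisson(lam * dec)
        starts.extend(rng.integers(pos - zone_length, pos + zone_length, size=n))
    starts.extend(rng.integers(0, chrom_length, size=n_background))
    starts = np.clip(np.array(starts, dtype=np.int64), 0, chrom_length - 100)
    regions = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 100}
    ).sort_values("start").reset_index(drop=True)
    return genes, regions
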