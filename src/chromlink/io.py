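"""Readers and writers for the pipeline's tabular formats.

All genomic coordinates are 0-based half-open internally and in every file
this package writes. 1-based inputs (GTF) are converted exactly once, at
parse time. Interval files round-trip losslessly through their canonical
(sorted) form.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("chromlink")

STRANDS = {"+", "-"}
#: gene class labels
GENE_CLASSES = ("DEG_ect", "DEG_end", "DEG_mes", "SEG", "unclassified")

_ANNOTATION_COLS = ["gene_id", "chrom", "strand", "tss"]
_EXPR_COLS = ["GE_ect", "GE_end", "GE_mes"]


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


def _is_gtf(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return len(line.rstrip("\n").split("\t")) == 9
    return False


def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation as TSV (gene_id, chrom, strand, tss) or GTF.

    For GTF input the TSS of a gene is the most 5' transcript start across
    its records: the minimal start on the + strand, the maximal end on the
    - strand (converted to a 0-based position). Output is sorted by
    (chrom, tss); duplicated gene_ids are rejected.
    """
    path = Path(path)
    if _is_gtf(path):
        df = _read_annotation_gtf(path)
    else:
        df = _read_annotation_tsv(path)
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicated gene_id(s): {sorted(set(dup))[:5]}")
    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        raise FormatError(f"unknown strand symbol {df.loc[bad, 'strand'].iloc[0]!r}")
    if (df["tss"] < 0).any():
        raise FormatError("negative TSS position")
    df = df.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)
    logger.info("read %d gene annotations from %s", len(df), path)
    return df[_ANNOTATION_COLS]


def _read_annotation_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in _ANNOTATION_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = df["tss"].isna() | ~df["tss"].astype(str).str.fullmatch(r"-?\d+")
    if bad.any():
        # +2: header line plus 1-based numbering
        raise FormatError(f"{path}: malformed row at line {int(bad.idxmax()) + 2}")
    df["tss"] = df["tss"].astype(np.int64)
    return df


def _read_annotation_gtf(path: Path) -> pd.DataFrame:
    records: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: malformed GTF row at line {lineno}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature not in ("transcript", "mRNA", "gene", "exon"):
                continue
            if strand not in STRANDS:
                raise FormatError(f"{path}: unknown strand at line {lineno}")
            gid = _parse_gtf_attributes(attrs).get("gene_id")
            if gid is None:
                raise FormatError(f"{path}: missing gene_id at line {lineno}")
            start_i, end_i = int(start), int(end)
            # GTF is 1-based inclusive: 0-based TSS is start-1 (+) or end-1 (-)
            tss = start_i - 1 if strand == "+" else end_i - 1
            rec = records.get(gid)
            if rec is None:
                records[gid] = {"chrom": chrom, "strand": strand, "tss": tss}
            else:
                if strand == "+":
                    rec["tss"] = min(rec["tss"], tss)
                else:
                    rec["tss"] = max(rec["tss"], tss)
    df = pd.DataFrame(
        [{"gene_id": g, **r} for g, r in records.items()],
        columns=_ANNOTATION_COLS,
    )
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a pseudo-bulk expression table (log2 RPKM per lineage).

    Columns: gene_id, GE_ect, GE_end, GE_mes. Values may be negative
    (log2 of RPKM < 1); missing cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ["gene_id"] + _EXPR_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df[_EXPR_COLS].isna().any().any():
        raise FormatError(f"{path}: missing expression values")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicated gene_id(s) in expression: {sorted(set(dup))[:5]}")
    return df[["gene_id"] + _EXPR_COLS].reset_index(drop=True)


def read_bed(path: str | Path, min_fields: int = 3) -> pd.DataFrame:
    """Read a BED3+ file; extra columns are preserved as metadata.

    Intervals with end <= start are rejected; unsorted input is sorted
    silently with a log entry.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < min_fields:
                raise FormatError(f"{path}: too few fields at line {lineno}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: malformed row at line {lineno}") from exc
            if end <= start or start < 0:
                raise FormatError(
                    f"{path}: invalid interval [{start},{end}) at line {lineno}"
                )
            rows.append([fields[0], start, end, *fields[3:]])
    ncol = max((len(r) for r in rows), default=3)
    cols = names[:ncol] + [f"extra_{i}" for i in range(len(names), ncol)]
    df = pd.DataFrame(rows, columns=cols)
    if len(df) == 0:
        df = pd.DataFrame(columns=cols or names[:3])
    else:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if not df.sort_values(["chrom", "start"]).index.equals(df.index):
            logger.info("%s: intervals unsorted, sorting", path)
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df


def read_tads(path: str | Path) -> pd.DataFrame:
    """Read TAD intervals from BED; overlapping TADs on a chromosome are rejected.

    A ``tad_id`` column is taken from the BED name field when present,
    otherwise synthesised as ``tad_<n>`` in genomic order.
    """
    df = read_bed(path)
    if "name" in df.columns and df["name"].notna().all():
        df = df.rename(columns={"name": "tad_id"})
    else:
        df["tad_id"] = [f"tad_{i:05d}" for i in range(len(df))]
    validate_tads(df)
    return df[["tad_id", "chrom", "start", "end"]]


def validate_tads(tads: pd.DataFrame) -> None:
    for chrom, sub in tads.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        overlap = sub["start"].values[1:] < sub["end"].values[:-1]
        if overlap.any():
            i = int(np.argmax(overlap))
            raise FormatError(
                f"overlapping TADs on {chrom} near position {sub['start'].values[1:][i]}"
            )


_WINDOW_BASE = ["chrom", "start", "end"]


def window_columns(lineages=("ect", "end", "mes")) -> list[str]:
    cols = list(_WINDOW_BASE)
    for lin in lineages:
        cols += [f"reads_{lin}", f"total_{lin}", f"meth_{lin}"]
    return cols


def read_windows(path: str | Path, width: int | None = None) -> pd.DataFrame:
    """Read a signal-window count table (accessibility or methylation).

    Columns per lineage: reads (coverage), total (GC or CG dinucleotide
    count), meth (methylated count). Enforces 0 <= meth <= total and, when
    ``width`` is given, a fixed window width.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in window_columns() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for lin in ("ect", "end", "mes"):
        if (df[f"meth_{lin}"] > df[f"total_{lin}"]).any():
            raise FormatError(f"{path}: meth_{lin} exceeds total_{lin}")
        for col in (f"reads_{lin}", f"total_{lin}", f"meth_{lin}"):
            if (df[col] < 0).any():
                raise FormatError(f"{path}: negative counts in {col}")
    if width is not None and len(df):
        bad = (df["end"] - df["start"]) != width
        if bad.any():
            raise FormatError(f"{path}: window width != {width} at row {int(bad.idxmax())}")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


CATALOGUE_COLS = [
    "chrom", "start", "end", "gene_id", "score", "strand",
    "lineage", "tad_id", "distance",
]


def write_catalogue(links: pd.DataFrame, path: str | Path) -> None:
    """Write a gene-region link catalogue as BED6+3.

    Row layout: region coords, name = gene_id, score = |distance|, strand of
    the gene, then lineage, tad_id and the signed TSS-to-region-centre
    distance. Rows are ordered by (chrom, start, gene_id).
    """
    df = links.copy()
    required = {"chrom", "start", "end", "gene_id", "strand", "lineage", "tad_id", "distance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalogue missing columns {sorted(missing)}")
    df["score"] = df["distance"].abs().astype(np.int64)
    df = df.sort_values(["chrom", "start", "gene_id"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CATALOGUE_COLS) + "\n")
        df[CATALOGUE_COLS].to_csv(fh, sep="\t", header=False, index=False)
    logger.info("wrote %d links to %s", len(df), path)


def read_catalogue(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=CATALOGUE_COLS, comment="#")
    for col in ("start", "end", "score", "distance"):
        if len(df):
            df[col] = df[col].astype(np.int64)
    return df


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write called regions as BED: name = ``lineage|class``, score = Dom*1000."""
    df = regions.copy()
    df["name"] = df["lineage"].astype(str) + "|" + df["region_class"].astype(str)
    df["score"] = (df["dominance"] * 1000).round().astype(int)
    df = df.sort_values(["chrom", "start"], kind="mergesort")
    df[["chrom", "start", "end", "name", "score"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_motif_list(path: str | Path) -> pd.DataFrame:
    """Read an enriched-motif table: motif, score, consensus, origin_gene."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["motif", "score", "consensus", "origin_gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["consensus"].isna().any() or (df["consensus"].astype(str).str.len() == 0).any():
        raise FormatError(f"{path}: empty consensus")
    if not np.isfinite(df["score"]).all():
        raise FormatError(f"{path}: non-finite score")
    return df[required]
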