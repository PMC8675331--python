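"""Readers and writers for the plain-text formats used across the pipeline.

Formats: BED6 and minimal GFF3 for gene models, a per-cytosine TSV
(chrom, pos, strand, context, count_methylated, count_total), genes x samples
expression matrices as TSV, and GMT gene-set collections.  All readers are
gzip-transparent (pandas/``gzip`` handle ``.gz`` suffixes); all table writers
emit deterministic row order.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Sequence

import pandas as pd

from .genome import GeneModel, GeneRegion

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------- gene models


def read_bed6(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (name column = gene id)."""
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            genes.append(GeneModel(name, chrom, int(start), int(end), strand))
    return genes


def read_gff3_genes(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Read gene features from a minimal GFF3; 1-based inclusive converted to
    0-based half-open on read.  The gene id is taken from the ID= attribute."""
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != feature:
                continue
            gid = None
            for field in attrs.split(";"):
                key, _, val = field.strip().partition("=")
                if key == "ID":
                    gid = val
                    break
            if gid is None:
                raise ValueError(f"{path}:{lineno}: {feature} feature without ID attribute")
            genes.append(GeneModel(gid, chrom, int(start) - 1, int(end), strand))
    return genes


def write_bed(path: str | Path, items: Sequence[GeneModel | GeneRegion]) -> None:
    """Write gene models or derived regions as BED6 (sorted by chrom, start, name)."""
    rows = []
    for it in items:
        name = it.gene_id if isinstance(it, GeneModel) else f"{it.gene_id}:{it.region_kind}"
        rows.append((it.chrom, it.start, it.end, name, 0, it.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


# ------------------------------------------------------------ cytosine tables


def read_cytosine_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine methylation count table."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "context": str})
    missing = set(CYTOSINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df["count_methylated"] > df["count_total"]
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} rows with count_methylated > count_total")
    return df[CYTOSINE_COLUMNS]


def write_cytosine_tsv(path: str | Path, records: pd.DataFrame) -> None:
    out = records[CYTOSINE_COLUMNS].sort_values(["chrom", "pos", "strand", "context"])
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------- expression tables


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def write_matrix_tsv(path: str | Path, matrix: pd.DataFrame, index_label: str = "gene_id") -> None:
    matrix.sort_index().to_csv(path, sep="\t", index_label=index_label)


def write_table_tsv(path: str | Path, table: pd.DataFrame, sort_by: list[str] | None = None) -> None:
    """Write a generic result table with a stable sort for diff-friendly output."""
    if sort_by:
        table = table.sort_values(sort_by, kind="mergesort")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ------------------------------------------------------------------ gene sets


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file: term_id -> (description, member gene ids)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need term, description, >=1 gene")
            term, desc, genes = parts[0], parts[1], frozenset(g for g in parts[2:] if g)
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term}")
            sets[term] = (desc, genes)
    return sets


def write_gmt(path: str | Path, sets: dict[str, tuple[str, frozenset[str]]]) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            desc, genes = sets[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")
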