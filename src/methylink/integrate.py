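"""Methylation-expression linkage and the nine-quadrant classification.

Within a sample, genes are binned by expression class and a metagene
methylation profile is computed per class; Spearman rank correlation links
per-gene region methylation to expression across genes.  Between two groups,
DEGs are intersected with DMGs, and each (gene, region) pair is placed in a
3x3 quadrant grid by its methylation-difference class (hypo / no-change /
hyper at |meth.diff| > 25 percentage points) and expression class (up /
no-change / down at |log2FC| > 1):

            hypo   nc   hyper
    up       Q1    Q2    Q3
    nc       Q4    Q5    Q6
    down     Q7    Q8    Q9

Both thresholds are strict, so boundary values land in the no-change class.
meth.diff is on the percentage-point scale (x100), making the DMR ratio
floor 0.25 and the quadrant floor 25 the same quantity in different units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, GeneRegion
from .methylome import DEFAULT_MIN_COVERAGE, metagene_profile
from .expression import expression_class


def gene_region_levels(
    records: pd.DataFrame,
    regions: list[GeneRegion],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    context: str | None = None,
) -> pd.DataFrame:
    """Coverage-weighted methylation level per (gene, region_kind).

    Returns a tidy frame gene_id, region_kind, level, n_covered; regions
    with no covered site get NaN.
    """
    sub = records if context is None else records[records["context"] == context]
    sub = sub[sub["count_total"] >= min_coverage]
    by_chrom = {}
    for chrom, g in sub.groupby("chrom"):
        g = g.sort_values("pos")
        by_chrom[chrom] = (
            g["pos"].to_numpy(),
            g["count_methylated"].to_numpy(),
            g["count_total"].to_numpy(),
        )
    rows = []
    for r in regions:
        if r.chrom not in by_chrom:
            rows.append((r.gene_id, r.region_kind, np.nan, 0))
            continue
        pos, m, t = by_chrom[r.chrom]
        lo, hi = np.searchsorted(pos, (r.start, r.end))
        if lo == hi:
            rows.append((r.gene_id, r.region_kind, np.nan, 0))
        else:
            rows.append((r.gene_id, r.region_kind, m[lo:hi].sum() / t[lo:hi].sum(), hi - lo))
    return pd.DataFrame(rows, columns=["gene_id", "region_kind", "level", "n_covered"])


def linkage_by_class(
    records: pd.DataFrame,
    genes: list[GeneModel],
    fpkm: pd.Series,
    n_bins_flank: int = 20,
    n_bins_body: int = 20,
    context: str | None = None,
    flank_bp: int = 2000,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Mean methylation profile per expression class.

    Genes are binned by their FPKM into none/low/middle/high and a metagene
    profile is computed per class over the 2 kb flanks and the body.  Empty
    classes are flagged absent (not emitted).  Columns: expression_class,
    zone, bin_index, mean_level, n_genes.
    """
    classes = expression_class(fpkm)
    out = []
    for cls in ("none", "low", "middle", "high"):
        members = [g for g in genes if classes.get(g.gene_id) == cls]
        if not members:
            continue
        prof = metagene_profile(
            records, members, n_bins_flank, n_bins_body, context, flank_bp, min_coverage
        )
        prof.insert(0, "expression_class", cls)
        out.append(prof)
    if not out:
        return pd.DataFrame(
            columns=["expression_class", "zone", "bin_index", "mean_level", "n_genes"]
        )
    return pd.concat(out, ignore_index=True)


def spearman_linkage(
    region_levels: pd.DataFrame, gene_expression: pd.Series
) -> pd.DataFrame:
    """Spearman rho between region methylation and expression across genes.

    One row per region kind with rho, the two-sided p, and n pairs; rho > 0
    flags a positive methylation-expression relationship.  Region kinds with
    < 3 defined pairs or a constant vector are flagged undefined (NaN).
    """
    rows = []
    for kind, sub in region_levels.groupby("region_kind", sort=True):
        merged = sub.dropna(subset=["level"]).set_index("gene_id")["level"]
        expr = gene_expression.reindex(merged.index).dropna()
        merged = merged.loc[expr.index]
        n = len(merged)
        if n < 3 or merged.nunique() == 1 or expr.nunique() == 1:
            rows.append((kind, np.nan, np.nan, n))
            continue
        rho, p = stats.spearmanr(merged.to_numpy(), expr.to_numpy())
        rows.append((kind, float(rho), float(p), n))
    return pd.DataFrame(rows, columns=["region_kind", "rho", "p", "n"])


@dataclass(frozen=True)
class OverlapSummary:
    """DEG x DMG intersection bookkeeping for one comparison."""

    common_genes: frozenset[str]
    n_deg: int
    n_dmg: int
    n_common: int
    pct_of_degs: float  # percentage of DEGs that are differentially methylated


def overlap_deg_dmg(de_results: pd.DataFrame, dmg_annotations: pd.DataFrame) -> OverlapSummary:
    """Intersect the DEG set with the DMG set of the same comparison."""
    degs = set(de_results.loc[de_results["is_deg"], "gene_id"])
    dmgs = set(dmg_annotations["gene_id"])
    common = frozenset(degs & dmgs)
    pct = 100.0 * len(common) / len(degs) if degs else float("nan")
    return OverlapSummary(common, len(degs), len(dmgs), len(common), pct)


def nine_quadrant(
    log2fc, meth_diff, fc_threshold: float = 1.0, md_threshold: float = 25.0
):
    """Quadrant 1-9 for (log2FC, meth.diff-in-percentage-points) pairs.

    Rows are expression classes from up (log2FC > fc_threshold) to down
    (< -fc_threshold); columns are methylation classes from hypo
    (meth_diff < -md_threshold) to hyper (> md_threshold).  Strict
    inequalities throughout: Q1 = (up, hypo) ... Q5 = centre ... Q9 =
    (down, hyper).  Accepts scalars or arrays; non-finite input is an error.
    """
    fc = np.asarray(log2fc, dtype=float)
    md = np.asarray(meth_diff, dtype=float)
    if not (np.isfinite(fc).all() and np.isfinite(md).all()):
        raise ValueError("log2fc and meth_diff must be finite")
    col = np.where(md < -md_threshold, 0, np.where(md > md_threshold, 2, 1))
    row = np.where(fc > fc_threshold, 0, np.where(fc < -fc_threshold, 2, 1))
    quad = 3 * row + col + 1
    if np.isscalar(log2fc) and np.isscalar(meth_diff):
        return int(quad)
    return quad


def quadrant_table(
    de_results: pd.DataFrame,
    region_meth_diff: pd.DataFrame,
    fc_threshold: float = 1.0,
    md_threshold: float = 25.0,
) -> pd.DataFrame:
    """Per-(gene, region) quadrant assignment for one comparison.

    ``region_meth_diff`` needs gene_id, region_kind and a meth_diff column in
    percentage points (e.g. ``region_diff`` from DMG annotation, renamed);
    log2FC comes from the DE stage of the same comparison.  Rows with
    undefined meth_diff are dropped.
    """
    md_col = "meth_diff" if "meth_diff" in region_meth_diff.columns else "region_diff"
    merged = region_meth_diff.rename(columns={md_col: "meth_diff"}).merge(
        de_results[["gene_id", "log2fc"]], on="gene_id"
    )
    merged = merged.dropna(subset=["meth_diff", "log2fc"]).reset_index(drop=True)
    merged["quadrant"] = nine_quadrant(
        merged["log2fc"].to_numpy(), merged["meth_diff"].to_numpy(), fc_threshold, md_threshold
    )
    return merged[["gene_id", "region_kind", "log2fc", "meth_diff", "quadrant"]]
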