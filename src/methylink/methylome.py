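"""Methylation-level summaries, methylated-cytosine calling, and metagene profiles.

Per-cytosine records live in a pandas DataFrame with columns
``chrom, pos, strand, context, count_methylated, count_total`` (0-based
positions; contexts CG/CHG/CHH).  Methylation level is the percentage of
methylated cytosines, i.e. the coverage-weighted ratio
sum(methylated) / sum(total) over covered sites — not the mean of per-site
ratios, though that variant is available via ``weighted=False``.

Methylated cytosines are called per site with a one-sided binomial test
against the bisulfite non-conversion error rate (conversion efficiency of
the treatment was >99%, hence the 0.01 default), with Benjamini-Hochberg
correction across all tested sites of a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: Minimum per-site read depth for a cytosine to enter any summary; shared
#: with the DMR stage's per-site coverage rule.
DEFAULT_MIN_COVERAGE = 4

DEFAULT_ERROR_RATE = 0.01


@dataclass(frozen=True)
class MethylationSummary:
    """A single methylation-level summary over a set of sites."""

    grouping_key: str
    context: str  # "CG" | "CHG" | "CHH" | "all"
    level: float  # NaN when undefined
    n_sites: int  # sites passing the filter
    n_covered: int  # of those, sites meeting the coverage floor
    defined: bool

    def __post_init__(self) -> None:
        if self.defined and not (0.0 <= self.level <= 1.0):
            raise ValueError(f"level {self.level} outside [0, 1]")


def binomial_tail_p(n_meth: np.ndarray, n_total: np.ndarray, error_rate: float) -> np.ndarray:
    """P(X >= n_meth) for X ~ Binomial(n_total, error_rate)."""
    return stats.binom.sf(np.asarray(n_meth) - 1, np.asarray(n_total), error_rate)


def call_methylated(
    records: pd.DataFrame,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = 0.05,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Call methylated cytosines with a binomial test against ``error_rate``.

    Returns a copy of the covered records with ``p``, ``q`` (BH across all
    tested sites) and a boolean ``methylated`` column (q <= alpha).  Sites
    below ``min_coverage`` are skipped; the skipped count is logged.
    """
    if not (0.0 < error_rate < 1.0):
        raise ValueError("error_rate must lie strictly between 0 and 1")
    covered = records["count_total"] >= min_coverage
    n_skipped = int((~covered).sum())
    if n_skipped:
        logger.info("call_methylated: skipped %d sites below coverage %d", n_skipped, min_coverage)
    out = records.loc[covered].copy()
    if out.empty:
        out["p"] = out["q"] = pd.Series(dtype=float)
        out["methylated"] = pd.Series(dtype=bool)
        return out
    p = binomial_tail_p(out["count_methylated"].to_numpy(), out["count_total"].to_numpy(), error_rate)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out["p"], out["q"] = p, q
    out["methylated"] = out["q"] <= alpha
    return out


def _filter(
    records: pd.DataFrame,
    context: str | None,
    chrom: str | None,
    interval: tuple[int, int] | None,
) -> pd.DataFrame:
    mask = pd.Series(True, index=records.index)
    if context is not None and context != "all":
        mask &= records["context"] == context
    if chrom is not None:
        mask &= records["chrom"] == chrom
    if interval is not None:
        mask &= (records["pos"] >= interval[0]) & (records["pos"] < interval[1])
    return records.loc[mask]


def methylation_level(
    records: pd.DataFrame,
    context: str | None = None,
    chrom: str | None = None,
    interval: tuple[int, int] | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    weighted: bool = True,
    grouping_key: str | None = None,
) -> MethylationSummary:
    """Coverage-weighted methylation level over sites passing the filter.

    With no covered sites the summary is flagged undefined (level NaN),
    never reported as zero.
    """
    sub = _filter(records, context, chrom, interval)
    cov = sub.loc[sub["count_total"] >= min_coverage]
    key = grouping_key or (chrom if chrom is not None else "genome")
    ctx = context or "all"
    if cov.empty:
        return MethylationSummary(key, ctx, float("nan"), len(sub), 0, False)
    if weighted:
        level = cov["count_methylated"].sum() / cov["count_total"].sum()
    else:
        level = (cov["count_methylated"] / cov["count_total"]).mean()
    return MethylationSummary(key, ctx, float(level), len(sub), len(cov), True)


def levels_by_chromosome(
    records: pd.DataFrame,
    context: str | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Per-chromosome methylation levels as a tidy frame."""
    rows = []
    for chrom in sorted(records["chrom"].unique()):
        s = methylation_level(records, context=context, chrom=chrom, min_coverage=min_coverage)
        rows.append((s.grouping_key, s.context, s.level, s.n_sites, s.n_covered))
    return pd.DataFrame(rows, columns=["chrom", "context", "level", "n_sites", "n_covered"])


def levels_by_context(
    records: pd.DataFrame, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> pd.DataFrame:
    rows = []
    for ctx in CONTEXTS:
        s = methylation_level(records, context=ctx, min_coverage=min_coverage)
        rows.append((ctx, s.level, s.n_sites, s.n_covered))
    return pd.DataFrame(rows, columns=["context", "level", "n_sites", "n_covered"])


# --------------------------------------------------------------- metagene


def metagene_profile(
    records: pd.DataFrame,
    genes: list[GeneModel],
    n_bins_flank: int = 20,
    n_bins_body: int = 20,
    context: str | None = None,
    flank_bp: int = 2000,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Average methylation profile over 2 kb flanks and the gene body.

    Flank bins are fixed-width in genomic coordinates; body bins are
    proportional positions (each gene's length rescaled to [0, 1)), so a
    gene shorter than ``n_bins_body`` still contributes via proportional
    assignment.  Profiles are strand-oriented: bin 0 of the upstream zone
    is farthest from the TSS, and downstream bins increase away from the
    gene end.  The reported ``mean_level`` of a bin is the mean over genes
    of each gene's coverage-weighted level in that bin.

    Returns a frame with columns zone, bin_index, mean_level, n_genes.
    """
    if n_bins_flank < 1 or n_bins_body < 1 or not genes:
        raise ValueError("need >= 1 bin per zone and a non-empty gene list")
    sub = _filter(records, context, None, None)
    sub = sub.loc[sub["count_total"] >= min_coverage]
    by_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values("pos") for c, g in sub.groupby("chrom")
    }
    zones = ("upstream2k", "body", "downstream2k")
    nbin = {"upstream2k": n_bins_flank, "body": n_bins_body, "downstream2k": n_bins_flank}
    level_sum = {z: np.zeros(nbin[z]) for z in zones}
    gene_n = {z: np.zeros(nbin[z], dtype=int) for z in zones}
    w = flank_bp / n_bins_flank  # flank bin width, bp

    for gene in genes:
        chrom = by_chrom.get(gene.chrom)
        if chrom is None:
            continue
        pos = chrom["pos"].to_numpy()
        lo = np.searchsorted(pos, gene.start - flank_bp)
        hi = np.searchsorted(pos, gene.end + flank_bp)
        if lo == hi:
            continue
        p = pos[lo:hi]
        m = chrom["count_methylated"].to_numpy()[lo:hi]
        t = chrom["count_total"].to_numpy()[lo:hi]

        in_body = (p >= gene.start) & (p < gene.end)
        left = p < gene.start
        # proportional body position, strand-oriented
        rel = (p - gene.start + 0.5) / gene.length_bp
        if gene.strand == "-":
            rel = 1.0 - rel
        body_bin = np.clip((rel * n_bins_body).astype(int), 0, n_bins_body - 1)
        # flank bins by distance from the gene edge
        left_dist = gene.start - 1 - p  # 0 = adjacent to TSS side for + strand
        right_dist = p - gene.end
        if gene.strand == "+":
            up_mask, down_mask = left, ~left & ~in_body
            up_bin = n_bins_flank - 1 - np.clip((left_dist / w).astype(int), 0, n_bins_flank - 1)
            down_bin = np.clip((right_dist / w).astype(int), 0, n_bins_flank - 1)
        else:
            up_mask, down_mask = ~left & ~in_body, left
            up_bin = n_bins_flank - 1 - np.clip((right_dist / w).astype(int), 0, n_bins_flank - 1)
            down_bin = np.clip((left_dist / w).astype(int), 0, n_bins_flank - 1)

        for zone, mask, bins in (
            ("upstream2k", up_mask, up_bin),
            ("body", in_body, body_bin),
            ("downstream2k", down_mask, down_bin),
        ):
            if not mask.any():
                continue
            msum = np.bincount(bins[mask], weights=m[mask], minlength=nbin[zone])
            tsum = np.bincount(bins[mask], weights=t[mask], minlength=nbin[zone])
            have = tsum > 0
            level_sum[zone][have] += msum[have] / tsum[have]
            gene_n[zone][have] += 1

    rows = []
    for zone in zones:
        for b in range(nbin[zone]):
            n = gene_n[zone][b]
            rows.append((zone, b, level_sum[zone][b] / n if n else float("nan"), int(n)))
    return pd.DataFrame(rows, columns=["zone", "bin_index", "mean_level", "n_genes"])
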