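"""Windowed differential-methylation testing and DMR -> gene annotation.

The genome is tiled into fixed non-overlapping windows (200 bp by default,
anchored at coordinate 0).  Within a window, per-site counts are pooled per
group over cytosines that meet the per-site coverage floor in *both* groups,
and a two-sided exact test on the pooled 2x2 table gives the p-value.  BH
correction runs per sequence context across all emitted windows, and a
window is a DMR when it satisfies its context's acceptance triplet
(site-count floor, |difference| floor, q ceiling):

=======  =========  ==========  ==========
context  min sites  min |diff|  max q
=======  =========  ==========  ==========
CG       5          0.25        0.05
CHG      5          0.25        0.05
CHH      15         0.15        0.05
allC     20         0.20        0.05
=======  =========  ==========  ==========

The difference sign convention is group1 - group2, matching "G1-vs-G2"
comparison naming.  A gene is differentially methylated (DMG) when at least
one DMR overlaps its upstream-2k, body, or downstream-2k region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._exact import exact_test_2x2
from .genome import GeneRegion
from .methylome import DEFAULT_MIN_COVERAGE

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 200


@dataclass(frozen=True)
class ContextThresholds:
    """Per-context DMR acceptance triplet."""

    min_sites: int
    min_abs_diff: float
    max_q: float


CONTEXT_THRESHOLDS: dict[str, ContextThresholds] = {
    "CG": ContextThresholds(5, 0.25, 0.05),
    "CHG": ContextThresholds(5, 0.25, 0.05),
    "CHH": ContextThresholds(15, 0.15, 0.05),
    "allC": ContextThresholds(20, 0.20, 0.05),
}

WINDOW_COLUMNS = [
    "chrom", "start", "end", "context", "n_sites",
    "level_g1", "level_g2", "diff", "p",
]


def window_tests(
    g1_records: pd.DataFrame,
    g2_records: pd.DataFrame,
    context: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    thresholds: ContextThresholds | None = None,
) -> pd.DataFrame:
    """Pool and test all windows of one context between two groups.

    Only sites covered at >= ``min_coverage`` in both groups count; windows
    below the context's site floor, or with zero pooled coverage in either
    group, are not emitted (the latter is logged).  Returns one row per
    emitted window with pooled levels, diff = level_g1 - level_g2, and the
    exact-test p-value.
    """
    if thresholds is None:
        thresholds = _lookup_thresholds(context)
    key = ["chrom", "pos", "strand"] if context == "allC" else ["chrom", "pos", "strand", "context"]
    g1 = g1_records if context == "allC" else g1_records[g1_records["context"] == context]
    g2 = g2_records if context == "allC" else g2_records[g2_records["context"] == context]
    merged = g1.merge(g2, on=key, suffixes=("_1", "_2"))
    merged = merged[
        (merged["count_total_1"] >= min_coverage) & (merged["count_total_2"] >= min_coverage)
    ]
    if merged.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)

    win = merged["pos"] // window_bp
    grouped = merged.groupby([merged["chrom"], win], sort=True)
    agg = grouped.agg(
        m1=("count_methylated_1", "sum"),
        t1=("count_total_1", "sum"),
        m2=("count_methylated_2", "sum"),
        t2=("count_total_2", "sum"),
        n_sites=("pos", "size"),
    ).reset_index(names=["chrom", "window"])

    dead = (agg["t1"] == 0) | (agg["t2"] == 0)
    if dead.any():
        logger.info("window_tests(%s): skipped %d windows with zero coverage", context, int(dead.sum()))
        agg = agg[~dead]
    agg = agg[agg["n_sites"] >= thresholds.min_sites]
    if agg.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)

    p = exact_test_2x2(
        agg["m1"].to_numpy(), agg["t1"].to_numpy(), agg["m2"].to_numpy(), agg["t2"].to_numpy()
    )
    out = pd.DataFrame(
        {
            "chrom": agg["chrom"].to_numpy(),
            "start": (agg["window"] * window_bp).astype(int).to_numpy(),
            "end": ((agg["window"] + 1) * window_bp).astype(int).to_numpy(),
            "context": context,
            "n_sites": agg["n_sites"].to_numpy(),
            "level_g1": (agg["m1"] / agg["t1"]).to_numpy(),
            "level_g2": (agg["m2"] / agg["t2"]).to_numpy(),
            "p": p,
        }
    )
    out.insert(7, "diff", out["level_g1"] - out["level_g2"])
    return out.sort_values(["chrom", "start"], ignore_index=True)


def call_dmrs(
    tests: pd.DataFrame,
    context: str,
    thresholds: ContextThresholds | None = None,
) -> pd.DataFrame:
    """BH-correct emitted windows of one context and apply its acceptance rule.

    Returns the accepted windows with a ``q`` column; the q-values are
    computed across *all* emitted windows of the context (one testing
    family per context per comparison).
    """
    if thresholds is None:
        thresholds = _lookup_thresholds(context)
    if tests.empty:
        out = tests.copy()
        out["q"] = pd.Series(dtype=float)
        return out
    tests = tests.copy()
    _, tests["q"], _, _ = multipletests(tests["p"].to_numpy(), method="fdr_bh")
    keep = (
        (tests["n_sites"] >= thresholds.min_sites)
        & (tests["diff"].abs() >= thresholds.min_abs_diff)
        & (tests["q"] <= thresholds.max_q)
    )
    return tests.loc[keep].reset_index(drop=True)


def _lookup_thresholds(context: str) -> ContextThresholds:
    try:
        return CONTEXT_THRESHOLDS[context]
    except KeyError:
        raise ValueError(
            f"unknown context {context!r}; expected one of {sorted(CONTEXT_THRESHOLDS)}"
        ) from None


# ------------------------------------------------------------- annotation


def annotate_dmgs(
    dmrs: pd.DataFrame,
    regions: list[GeneRegion],
    g1_records: pd.DataFrame | None = None,
    g2_records: pd.DataFrame | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Annotate DMRs to gene regions by half-open interval overlap.

    A gene is a DMG when >= 1 DMR overlaps >= 1 of its three regions; one
    output row per (gene, region_kind) hit, listing the overlapping DMR ids
    ("chrom:start-end:context") and the region-wide methylation difference
    in percentage points.  When per-cytosine records of both groups are
    supplied the region difference is the coverage-weighted difference of
    pooled levels over the whole region; otherwise it falls back to the
    site-weighted mean of the overlapping DMR differences.
    """
    rows = []
    if dmrs.empty:
        return pd.DataFrame(columns=["gene_id", "region_kind", "dmr_ids", "n_dmrs", "region_diff"])
    by_chrom = {c: g for c, g in dmrs.groupby("chrom")}
    for region in regions:
        sub = by_chrom.get(region.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] < region.end) & (sub["end"] > region.start)]
        if hit.empty:
            continue
        ids = ";".join(
            f"{r.chrom}:{r.start}-{r.end}:{r.context}" for r in hit.itertuples()
        )
        if g1_records is not None and g2_records is not None:
            diff = _region_diff(region, g1_records, g2_records, min_coverage)
        else:
            diff = float(np.average(hit["diff"], weights=hit["n_sites"])) * 100.0
        rows.append((region.gene_id, region.region_kind, ids, len(hit), diff))
    return pd.DataFrame(rows, columns=["gene_id", "region_kind", "dmr_ids", "n_dmrs", "region_diff"])


def _region_diff(
    region: GeneRegion,
    g1_records: pd.DataFrame,
    g2_records: pd.DataFrame,
    min_coverage: int,
) -> float:
    from .methylome import methylation_level

    l1 = methylation_level(
        g1_records, chrom=region.chrom, interval=(region.start, region.end), min_coverage=min_coverage
    )
    l2 = methylation_level(
        g2_records, chrom=region.chrom, interval=(region.start, region.end), min_coverage=min_coverage
    )
    if not (l1.defined and l2.defined):
        return float("nan")
    return 100.0 * (l1.level - l2.level)
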