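"""FPKM computation, two-group differential expression, and expression classes.

FPKM = count x 10^9 / (gene length in bp x total mapped fragments).  The
differential-expression stage is a deliberately simple, pluggable two-sample
test (Welch t on log2(FPKM + pseudocount), BH across genes); what the
pipeline actually consumes downstream is the DEG filter |log2FC| > 1 with
q < 0.05 (both inequalities strict) and the per-gene log2 fold changes.
Expression classes follow the RPKM bins: none (<= 1), low (1, 10],
middle (10, 100], high (> 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXPRESSION_CLASSES = ("none", "low", "middle", "high")


def fpkm(
    counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    total_mapped: pd.Series | None = None,
) -> pd.DataFrame:
    """Convert a genes x samples count matrix to FPKM.

    ``total_mapped`` defaults to the per-sample column sums of ``counts``.
    Every counted gene must have a positive length.
    """
    missing = counts.index.difference(gene_lengths_bp.index)
    if len(missing):
        raise ValueError(f"no length for {len(missing)} genes, e.g. {list(missing[:3])}")
    lengths = gene_lengths_bp.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if total_mapped is None:
        total_mapped = counts.sum(axis=0)
    total_mapped = total_mapped.loc[counts.columns].astype(float)
    if (total_mapped <= 0).any():
        raise ValueError("total mapped counts must be positive")
    return counts * 1e9 / np.outer(lengths, total_mapped)


@dataclass(frozen=True)
class DEParams:
    fc_threshold: float = 1.0  # on the log2 scale
    q_threshold: float = 0.05
    pseudocount: float = 1.0  # on the FPKM scale


def differential_expression(
    matrix: pd.DataFrame,
    group1_samples: list[str],
    group2_samples: list[str],
    params: DEParams = DEParams(),
) -> pd.DataFrame:
    """Two-group differential expression on an FPKM matrix.

    log2FC = log2((mean1 + pc) / (mean2 + pc)), group1 over group2 (the
    "G1-vs-G2" convention).  With >= 2 replicates per group a Welch t-test
    on log2(FPKM + pc) gives p, BH across genes gives q, and
    is_deg <=> |log2FC| > fc_threshold and q < q_threshold (strict).  With
    fewer replicates the result degrades to fold-change-only (p/q NaN,
    is_deg False) with an explicit warning.
    """
    overlap = set(group1_samples) & set(group2_samples)
    if overlap:
        raise ValueError(f"groups share samples: {sorted(overlap)}")
    x1 = matrix[list(group1_samples)].to_numpy(dtype=float)
    x2 = matrix[list(group2_samples)].to_numpy(dtype=float)
    pc = params.pseudocount
    log2fc = np.log2(x1.mean(axis=1) + pc) - np.log2(x2.mean(axis=1) + pc)

    out = pd.DataFrame({"gene_id": matrix.index, "log2fc": log2fc})
    if x1.shape[1] < 2 or x2.shape[1] < 2:
        logger.warning(
            "differential_expression: <2 replicates in a group; fold-change-only mode, no p/q"
        )
        out["p"] = out["q"] = np.nan
        out["is_deg"] = False
        return out

    t, p = stats.ttest_ind(np.log2(x1 + pc), np.log2(x2 + pc), axis=1, equal_var=False)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        _, q[ok], _, _ = multipletests(p[ok], method="fdr_bh")
    out["p"], out["q"] = p, q
    out["is_deg"] = (np.abs(log2fc) > params.fc_threshold) & (q < params.q_threshold)
    return out


def expression_class(fpkm_value):
    """Bin FPKM into none (<=1), low (1,10], middle (10,100], high (>100).

    Accepts a scalar or an array/Series; negative input is an error.
    """
    arr = np.asarray(fpkm_value, dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM values must be non-negative")
    classes = np.select(
        [arr <= 1.0, arr <= 10.0, arr <= 100.0], ["none", "low", "middle"], default="high"
    )
    if np.isscalar(fpkm_value) or arr.ndim == 0:
        return str(classes)
    if isinstance(fpkm_value, pd.Series):
        return pd.Series(classes, index=fpkm_value.index)
    return classes


def pathway_coverage(n_de_in_pathway: int, n_pathway_genes: int) -> float:
    """Percentage of a pathway's genes that are differentially expressed,
    to two decimals."""
    if n_pathway_genes <= 0:
        raise ValueError("pathway must contain at least one gene")
    if not (0 <= n_de_in_pathway <= n_pathway_genes):
        raise ValueError("need 0 <= n_de <= n_pathway")
    return round(100.0 * n_de_in_pathway / n_pathway_genes, 2)
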