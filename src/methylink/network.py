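"""Weighted co-expression network analysis: adjacency, topological overlap,
module detection, eigengenes, module-trait correlation, and hub selection.

The construction follows the standard weighted-network recipe: a soft-power
adjacency a_ij = |cor(x_i, x_j)|^power (power 8, unsigned by default; a
signed mode ((1 + cor)/2)^power is available), the topological overlap
matrix

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage hierarchical clustering of the dissimilarity 1 - TOM with a
static height cut, and a minimum module size of 50 (smaller clusters are
relabelled "unassigned").  A module eigengene is the first principal
component of the module's per-gene standardized expression, oriented so it
correlates non-negatively with the module's mean profile.  Gene significance
(GS) is the signed Pearson correlation of a gene with a trait; module
membership (MM) is its correlation with its own module eigengene; "weight"
between two genes is their TOM entry.  Hub genes are selected by joint GS,
MM and weight thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class NetworkParams:
    power: int = 8
    min_module_size: int = 50
    signed: bool = False
    #: static cut height on the 1-TOM dissimilarity dendrogram; with a soft
    #: power of 8, within-module joins complete below ~0.95 while merges
    #: between distinct modules approach 1, so the cut sits between the two.
    cut_height: float = 0.96

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModuleResult:
    """Bundle of a full network analysis on one expression matrix."""

    labels: pd.Series  # gene -> module label (UNASSIGNED allowed)
    eigengenes: pd.DataFrame  # module x sample
    tom: pd.DataFrame  # gene x gene topological overlap
    gene_significance: pd.DataFrame = field(default=None)  # gene x trait
    module_membership: pd.Series = field(default=None)  # gene -> cor with own ME
    module_trait_r: pd.DataFrame = field(default=None)  # module x trait
    module_trait_p: pd.DataFrame = field(default=None)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.index]


def adjacency(matrix: pd.DataFrame, params: NetworkParams = NetworkParams()) -> pd.DataFrame:
    """Soft-threshold adjacency from a genes x samples matrix.

    Genes with zero variance across samples are removed with a warning;
    fewer than three samples is an error.
    """
    if matrix.shape[1] < 3:
        raise ValueError("adjacency needs >= 3 samples")
    var = matrix.var(axis=1)
    keep = var > 0
    if (~keep).any():
        logger.warning("adjacency: dropping %d zero-variance genes", int((~keep).sum()))
        matrix = matrix.loc[keep]
    cor = np.corrcoef(matrix.to_numpy(dtype=float))
    if params.signed:
        a = ((1.0 + cor) / 2.0) ** params.power
    else:
        a = np.abs(cor) ** params.power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=matrix.index, columns=matrix.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix from a symmetric adjacency in [0, 1]."""
    a = adj.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)  # connectivity and shared-neighbour sums exclude self
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(tom: pd.DataFrame, params: NetworkParams = NetworkParams()) -> pd.Series:
    """Cluster 1 - TOM by average linkage and cut at a static height.

    Clusters smaller than ``min_module_size`` become UNASSIGNED; surviving
    modules are named M1, M2, ... in decreasing size order.
    """
    genes = tom.index
    if len(genes) < 2:
        return pd.Series([UNASSIGNED] * len(genes), index=genes, name="module")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(z, t=params.cut_height, criterion="distance")
    counts = pd.Series(raw).value_counts()
    big = counts[counts >= params.min_module_size].index
    if len(big) == 1 and counts.sum() == counts[big[0]]:
        logger.warning("detect_modules: all genes fall in a single module")
    order = sorted(big, key=lambda c: (-counts[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(order)}
    labels = pd.Series(
        [rename.get(c, UNASSIGNED) for c in raw], index=genes, name="module"
    )
    return labels


def module_eigengene(matrix: pd.DataFrame, module_genes: list[str]) -> pd.Series:
    """First principal component of the z-scored module submatrix, as a
    per-sample profile oriented to correlate non-negatively with the module
    mean expression."""
    if len(module_genes) < 2:
        raise ValueError("a module needs >= 2 genes")
    sub = matrix.loc[module_genes].astype(float)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("module has no non-constant genes")
    if (~keep).any():
        logger.warning("module_eigengene: excluding %d constant genes", int((~keep).sum()))
        sub, sd = sub.loc[keep], sd[keep]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).to_numpy()
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    if np.corrcoef(eig, z.mean(axis=0))[0, 1] < 0:
        eig = -eig
    return pd.Series(eig, index=matrix.columns, name="eigengene")


def eigengene_matrix(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """module x sample eigengene table for every assigned module."""
    mods = sorted(set(labels) - {UNASSIGNED})
    rows = {m: module_eigengene(matrix, list(labels.index[labels == m])) for m in mods}
    return pd.DataFrame(rows).T.reindex(mods)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson module-trait correlations with two-sided t-based p-values.

    Constant traits yield NaN (flagged undefined) rather than an error.
    """
    if eigengenes.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    traits = traits.loc[eigengenes.columns]
    r = pd.DataFrame(index=eigengenes.index, columns=traits.columns, dtype=float)
    p = r.copy()
    for mod in eigengenes.index:
        for trait in traits.columns:
            t = traits[trait].to_numpy(dtype=float)
            if np.ptp(t) == 0:
                r.loc[mod, trait] = p.loc[mod, trait] = np.nan
                continue
            res = stats.pearsonr(eigengenes.loc[mod].to_numpy(), t)
            r.loc[mod, trait], p.loc[mod, trait] = res.statistic, res.pvalue
    return r, p


def flag_extreme_modules(module_trait_r: pd.DataFrame, trait: str) -> tuple[str, str]:
    """(most-positive, most-negative) module for one trait."""
    col = module_trait_r[trait].dropna()
    if col.empty:
        raise ValueError(f"no defined correlations for trait {trait!r}")
    return str(col.idxmax()), str(col.idxmin())


def gene_significance(matrix: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Signed Pearson correlation of each gene with each trait (gene x trait)."""
    traits = traits.loc[matrix.columns]
    x = matrix.to_numpy(dtype=float)
    xz = x - x.mean(axis=1, keepdims=True)
    xn = np.sqrt((xz**2).sum(axis=1))
    out = {}
    for trait in traits.columns:
        t = traits[trait].to_numpy(dtype=float)
        tz = t - t.mean()
        tn = np.sqrt((tz**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            out[trait] = (xz @ tz) / (xn * tn)
    return pd.DataFrame(out, index=matrix.index)


def module_membership(
    matrix: pd.DataFrame, labels: pd.Series, eigengenes: pd.DataFrame
) -> pd.Series:
    """Correlation of each assigned gene with its own module eigengene."""
    mm = pd.Series(np.nan, index=matrix.index, name="mm")
    for mod in eigengenes.index:
        genes = labels.index[labels == mod]
        if not len(genes):
            continue
        gs = gene_significance(matrix.loc[genes], eigengenes.loc[[mod]].T)
        mm.loc[genes] = gs[mod]
    return mm


@dataclass(frozen=True)
class HubCriteria:
    """Joint thresholds for hub-gene selection within one module.

    ``gs_direction`` "above" keeps genes with both GS values strictly above
    ``gs_threshold`` (positively trait-coupled modules); "below" keeps genes
    strictly below it (negatively coupled modules).
    """

    gs_threshold: float = 0.50
    gs_direction: str = "above"
    mm_threshold: float = 0.90
    weight_threshold: float = 0.60

    def __post_init__(self) -> None:
        if self.gs_direction not in ("above", "below"):
            raise ValueError("gs_direction must be 'above' or 'below'")


def select_hub_genes(
    result: ModuleResult,
    module: str,
    criteria: HubCriteria,
    traits: tuple[str, str] = ("length", "weight"),
) -> tuple[list[str], pd.DataFrame, str | None]:
    """Select hub genes of one module and their retained network edges.

    Returns (selected genes, edge frame [source, target, weight], top hub =
    gene of maximal degree among retained edges, or None).  An empty
    selection is a valid outcome.
    """
    genes = result.labels.index[result.labels == module]
    gs = result.gene_significance.loc[genes, list(traits)]
    mm = result.module_membership.loc[genes]
    if criteria.gs_direction == "above":
        gs_ok = (gs > criteria.gs_threshold).all(axis=1)
    else:
        gs_ok = (gs < criteria.gs_threshold).all(axis=1)
    selected = sorted(genes[(gs_ok & (mm > criteria.mm_threshold)).to_numpy()])

    rows = []
    for i, gi in enumerate(selected):
        for gj in selected[i + 1 :]:
            w = float(result.tom.loc[gi, gj])
            if w > criteria.weight_threshold:
                rows.append((gi, gj, w))
    edges = pd.DataFrame(rows, columns=["source", "target", "weight"])
    top = None
    if not edges.empty:
        degree = pd.concat([edges["source"], edges["target"]]).value_counts()
        top = str(degree.index[0])
    return selected, edges, top


def build_network(
    matrix: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    params: NetworkParams = NetworkParams(),
) -> ModuleResult:
    """Run the full module-detection chain on a genes x samples matrix."""
    adj = adjacency(matrix, params)
    tom = topological_overlap(adj)
    labels = detect_modules(tom, params)
    labels = labels.reindex(matrix.index, fill_value=UNASSIGNED)
    me = eigengene_matrix(matrix.loc[tom.index], labels.loc[tom.index])
    result = ModuleResult(labels=labels, eigengenes=me, tom=tom)
    result.module_membership = module_membership(matrix.loc[tom.index], labels.loc[tom.index], me)
    if traits is not None:
        result.gene_significance = gene_significance(matrix, traits)
        result.module_trait_r, result.module_trait_p = module_trait_correlation(me, traits)
    return result
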