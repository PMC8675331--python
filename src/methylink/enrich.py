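"""Hypergeometric gene-set over-representation with BH correction.

Given a query gene list and a collection of gene sets (GO terms, KEGG
pathways, ... read from GMT), each term is tested for enrichment against
the background universe with the upper-tail hypergeometric probability
P(X >= k) for k query hits in a term of size K, a query of size n, and a
universe of size N.  Terms with BH-corrected FDR < 0.05 are flagged
significantly enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """term_id -> (name, members), with a background universe.

    The universe defaults to the union of all term members (the "genome
    background" of annotated genes); members outside an explicit universe
    are filtered out, and terms left empty are dropped with a warning.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default=None)

    def __post_init__(self) -> None:
        if self.universe is None:
            self.universe = frozenset().union(*(g for _, g in self.sets.values())) if self.sets else frozenset()
        else:
            self.universe = frozenset(self.universe)
            filtered = {}
            for term, (name, genes) in self.sets.items():
                kept = genes & self.universe
                if not kept:
                    logger.warning("dropping term %s: no members in universe", term)
                    continue
                filtered[term] = (name, kept)
            self.sets = filtered

    @classmethod
    def from_gmt(cls, path, universe=None) -> "GeneSetCollection":
        from .io import read_gmt

        return cls(read_gmt(path), universe)


def hypergeom_enrich(
    query_genes,
    collection: GeneSetCollection,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Over-representation test for every term of the collection.

    Query genes outside the universe are dropped (count logged).  Returns a
    frame sorted by p with columns term_id, term_name, k, K, n, N, p, q,
    significant (q < q_threshold).
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene list")
    if not collection.universe:
        raise ValueError("empty background universe")
    stray = query - set(collection.universe)
    if stray:
        logger.info("hypergeom_enrich: dropped %d query genes outside the universe", len(stray))
        query -= stray
    if not query:
        raise ValueError("no query genes inside the universe")

    N, n = len(collection.universe), len(query)
    rows = []
    for term, (name, members) in collection.sets.items():
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append((term, name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    _, out["q"], _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["p", "term_id"], ignore_index=True)
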