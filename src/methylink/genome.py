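"""Gene models and derivation of the three analysis regions per gene.

All coordinates are 0-based half-open throughout the package; BED input is
taken as-is and GFF3 (1-based inclusive) is converted on read.  Each gene
contributes three strand-aware analysis regions: a 2 kb upstream flank, the
gene body, and a 2 kb downstream flank.  For a minus-strand gene "upstream"
lies at higher genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

REGION_KINDS = ("upstream2k", "body", "downstream2k")

DEFAULT_FLANK_BP = 2000


class CoordinateError(ValueError):
    """A feature falls outside its chromosome or violates start < end."""


@dataclass(frozen=True)
class GeneModel:
    """A gene span on a chromosome, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRegion:
    """One of the three analysis regions derived from a gene."""

    gene_id: str
    region_kind: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def derive_regions(
    gene: GeneModel, flank_bp: int = DEFAULT_FLANK_BP, chrom_length: int | None = None
) -> list[GeneRegion]:
    """Derive upstream / body / downstream regions for one gene.

    Flanks span up to ``flank_bp`` and are clipped at chromosome bounds.
    Returns the three regions in (upstream2k, body, downstream2k) order.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    if chrom_length is not None and (gene.start < 0 or gene.end > chrom_length):
        raise CoordinateError(
            f"{gene.gene_id}: [{gene.start}, {gene.end}) outside chromosome of length {chrom_length}"
        )
    hi = chrom_length if chrom_length is not None else gene.end + flank_bp
    left = (max(0, gene.start - flank_bp), gene.start)
    right = (gene.end, min(hi, gene.end + flank_bp))
    if gene.strand == "+":
        up, down = left, right
    else:
        up, down = right, left

    def _mk(kind: str, span: tuple[int, int]) -> GeneRegion:
        return GeneRegion(gene.gene_id, kind, gene.chrom, span[0], span[1], gene.strand)

    return [_mk("upstream2k", up), _mk("body", (gene.start, gene.end)), _mk("downstream2k", down)]


def derive_all_regions(
    genes: Iterable[GeneModel],
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GeneRegion]:
    """derive_regions over a collection, clipping against per-chromosome lengths."""
    out: list[GeneRegion] = []
    for g in genes:
        clen = chrom_lengths.get(g.chrom) if chrom_lengths else None
        out.extend(derive_regions(g, flank_bp, clen))
    return out


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    )


def regions_to_frame(regions: Sequence[GeneRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in regions],
            "region_kind": [r.region_kind for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "strand": [r.strand for r in regions],
        }
    )
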