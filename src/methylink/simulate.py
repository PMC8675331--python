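"""Seeded synthetic-data generator with planted, recoverable structure.

The generator emulates the statistical design of a three-sex-group (female,
male, pseudomale) flatfish study: a small genome with two autosomes plus Z
and W chromosomes, non-overlapping gene models with flank-safe gaps,
per-cytosine methylomes per group with CG/CHG/CHH contexts, overdispersed
sequencing depth, a W-chromosome hypermethylation bias in the pseudomale
group, a high-at-body-start / low-at-body-end CG gradient, planted DMRs of
known window, context and effect, an expression matrix with planted
co-expression modules coupled to growth traits (length, weight), planted
differentially expressed genes, and an optional linkage adjustment that
couples flank methylation negatively — and body methylation positively — to
a gene's expression class.

Every output is a pure function of (config, seed): independent random
streams are derived as ``default_rng([seed, stream_id])`` so that, e.g.,
cytosine site layout is shared across groups while read counts differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GeneModel

logger = logging.getLogger(__name__)

_TISSUE_LETTER = {"gonad": "G", "muscle": "M", "brain": "B", "liver": "L"}

# random stream ids (second word of the seed sequence)
_S_ANNOT, _S_SITES, _S_DMRS, _S_EXPR, _S_TRAITS, _S_COUNTS = 0, 1, 2, 3, 4, 100


@dataclass(frozen=True)
class PlantedDMR:
    chrom: str
    start: int
    end: int
    context: str
    effect: float  # added to the target group's true level inside the window
    group: str


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: minutes of runtime, every pipeline path exercised."""

    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 600_000, "chrZ": 600_000, "chrW": 600_000}
    )
    n_genes: int = 300
    gene_length: tuple[int, int] = (1000, 3000)
    gene_gap: tuple[int, int] = (4000, 6000)  # >= 2 x flank so regions never collide

    groups: tuple[str, ...] = ("F", "M", "PM")
    tissues: tuple[str, ...] = ("gonad", "muscle")
    replicates: int = 3

    # methylome
    baseline: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.75, "CHG": 0.10, "CHH": 0.05}
    )
    site_density: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.04, "CHG": 0.03, "CHH": 0.08}
    )
    site_noise_sd: float = 0.03  # per-site level jitter, shared across groups
    chrom_offsets: dict[str, float] = field(default_factory=lambda: {"chr2": -0.03})
    group_chrom_bias: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"PM": {"chrW": 0.10}}
    )
    body_gradient: float = 0.10  # CG level: + at body start, - at body end
    depth_mean: float = 30.0
    depth_size: float = 10.0  # NB size; variance = mean + mean^2 / size

    # planted DMRs
    window_bp: int = 200
    n_planted_dmrs: int = 50
    dmr_effect: float = -0.4
    dmr_context: str = "CG"
    dmr_group: str = "M"

    # expression / modules / traits
    module_sizes: tuple[int, ...] = (100, 100, 80)
    intra_cor: float = 0.8
    module_scale: float = 2.0  # log2-FPKM units of module signal
    #: per-module correlation of the latent factor with the growth latent;
    #: the first module is strongly positive, the second moderately negative
    #: (strong couplings of opposite sign to one trait would correlate the
    #: modules themselves and blur their boundary)
    trait_coupling: tuple[float, ...] = (0.9, -0.45, 0.0)
    n_planted_de: int = 12
    de_log2fc: float = 4.0
    de_group: str = "M"
    #: planted DE genes draw their baseline from the expressed range so the
    #: shift is not swallowed by the FPKM pseudocount
    de_base_log2fpkm: tuple[float, float] = (2.0, 7.0)
    base_log2fpkm: tuple[float, float] = (-2.0, 9.0)
    background_noise_sd: float = 0.5  # replicate noise of non-module genes, log2 units
    total_mapped: float = 2e7
    count_dispersion: float = 0.05

    # linkage plant: per expression class step (class index 0..3)
    linkage_flank_step: float = -0.08
    linkage_body_step: float = 0.05

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ------------------------------------------------------------------ annotation


def simulate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes with flank-safe gaps, round-robin over
    chromosomes.  Raises when the requested genes cannot be packed."""
    rng = np.random.default_rng([config.seed, _S_ANNOT])
    chroms = list(config.chromosomes)
    cursors = {c: 0 for c in chroms}
    genes: list[GeneModel] = []
    exhausted: set[str] = set()
    i = 0
    while len(genes) < config.n_genes:
        if len(exhausted) == len(chroms):
            raise ValueError(
                f"cannot pack {config.n_genes} genes into "
                f"{sum(config.chromosomes.values())} bp of chromosomes"
            )
        chrom = chroms[i % len(chroms)]
        i += 1
        if chrom in exhausted:
            continue
        gap = int(rng.integers(config.gene_gap[0], config.gene_gap[1] + 1))
        length = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
        start = cursors[chrom] + gap
        end = start + length
        if end + config.gene_gap[0] > config.chromosomes[chrom]:
            exhausted.add(chrom)
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{len(genes) + 1:04d}", chrom, start, end, strand))
        cursors[chrom] = end
    return genes


# -------------------------------------------------------------------- methylome


def plant_dmrs(config: SimulationConfig) -> list[PlantedDMR]:
    """Deterministic list of planted DMR windows, aligned to the window grid.

    Windows are drawn only among those whose (shared, seed-determined) site
    layout carries at least the context's site-count floor, so every planted
    DMR is testable under the pipeline's own emission rule.
    """
    if config.n_planted_dmrs == 0:
        return []
    from .dmr import CONTEXT_THRESHOLDS

    floor = CONTEXT_THRESHOLDS[config.dmr_context].min_sites
    sites = _site_positions(config)
    if config.dmr_context != "allC":
        sites = sites[sites["context"] == config.dmr_context]
    per_window = sites.groupby([sites["chrom"], sites["pos"] // config.window_bp]).size()
    eligible = sorted(per_window.index[per_window >= floor])
    if len(eligible) < config.n_planted_dmrs:
        raise ValueError(
            f"only {len(eligible)} windows carry >= {floor} {config.dmr_context} sites"
        )
    rng = np.random.default_rng([config.seed, _S_DMRS])
    picked = rng.choice(len(eligible), size=config.n_planted_dmrs, replace=False)
    return [
        PlantedDMR(
            eligible[i][0], int(eligible[i][1]) * config.window_bp,
            (int(eligible[i][1]) + 1) * config.window_bp,
            config.dmr_context, config.dmr_effect, config.dmr_group,
        )
        for i in sorted(picked)
    ]


def _site_positions(config: SimulationConfig) -> pd.DataFrame:
    """Cytosine site layout (chrom, pos, strand, context) shared across groups."""
    rng = np.random.default_rng([config.seed, _S_SITES])
    frames = []
    for chrom, length in config.chromosomes.items():
        for context, density in config.site_density.items():
            n = int(density * length)
            pos = np.sort(rng.choice(length, size=n, replace=False))
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": np.where(rng.random(n) < 0.5, "+", "-"),
                        "context": context,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _site_table(config: SimulationConfig, annotation: list[GeneModel]) -> pd.DataFrame:
    """Shared site layout with per-site base levels (group-independent)."""
    sites = _site_positions(config)
    rng = np.random.default_rng([config.seed, _S_SITES + 50])
    base = sites["context"].map(config.baseline).to_numpy(dtype=float)
    base += sites["chrom"].map(lambda c: config.chrom_offsets.get(c, 0.0)).to_numpy()
    base += rng.normal(0.0, config.site_noise_sd, len(sites))

    # CG gradient across gene bodies: high at body start, low at body end
    if config.body_gradient:
        rel = _body_relative_position(sites, annotation)
        in_body = ~np.isnan(rel)
        cg = (sites["context"] == "CG").to_numpy()
        adj = config.body_gradient * (1.0 - 2.0 * np.nan_to_num(rel))
        base = np.where(in_body & cg, base + adj, base)
    # keep base levels off the hard bounds so the per-site jitter stays
    # symmetric between groups (null windows remain exactly null)
    sites["base_level"] = np.clip(base, 0.01, 0.99)
    sites["body_rel"] = _body_relative_position(sites, annotation)
    return sites


def _body_relative_position(sites: pd.DataFrame, annotation: list[GeneModel]) -> np.ndarray:
    """Strand-oriented relative position in [0, 1) for sites inside a gene
    body, NaN elsewhere.  Genes never overlap, so a sorted interval lookup
    per chromosome suffices."""
    rel = np.full(len(sites), np.nan)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g.start)
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        strands = np.array([g.strand for g in genes])
        mask = (sites["chrom"] == chrom).to_numpy()
        pos = sites.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        r = np.full(len(pos), np.nan)
        gi = idx[ok]
        t = (pos[ok] - starts[gi] + 0.5) / (ends[gi] - starts[gi])
        t = np.where(strands[gi] == "-", 1.0 - t, t)
        r[ok] = t
        rel[mask] = r
    return rel


def simulate_methylome(
    config: SimulationConfig,
    annotation: list[GeneModel],
    group: str,
    linkage: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cytosine records for one group's pooled methylome library.

    Site layout (positions, strands, contexts, base levels) is shared across
    groups; the group contributes its chromosome bias, any planted DMR
    effects, the optional linkage adjustment, and its own depth / count
    draws.  Returns the standard cytosine-record frame.
    """
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}")
    sites = _site_table(config, annotation)
    level = sites["base_level"].to_numpy().copy()

    for chrom, offset in config.group_chrom_bias.get(group, {}).items():
        level += np.where(sites["chrom"].to_numpy() == chrom, offset, 0.0)

    for dmr in plant_dmrs(config):
        if dmr.group != group:
            continue
        hit = (
            (sites["chrom"].to_numpy() == dmr.chrom)
            & (sites["pos"].to_numpy() >= dmr.start)
            & (sites["pos"].to_numpy() < dmr.end)
        )
        if dmr.context != "allC":
            hit &= sites["context"].to_numpy() == dmr.context
        level = np.where(hit, level + dmr.effect, level)

    if linkage is not None:
        level = _apply_linkage(config, annotation, sites, level, linkage)

    clipped = np.clip(level, 0.0, 1.0)
    if (clipped != level).mean() > 0.02:
        logger.warning("simulate_methylome(%s): >2%% of site levels clamped to [0, 1]", group)

    rng = np.random.default_rng([config.seed, _S_COUNTS + list(config.groups).index(group)])
    p_depth = config.depth_size / (config.depth_size + config.depth_mean)
    depth = rng.negative_binomial(config.depth_size, p_depth, len(sites))
    meth = rng.binomial(depth, clipped)
    out = sites[["chrom", "pos", "strand", "context"]].copy()
    out["count_methylated"] = meth
    out["count_total"] = depth
    return out


def _apply_linkage(
    config: SimulationConfig,
    annotation: list[GeneModel],
    sites: pd.DataFrame,
    level: np.ndarray,
    linkage: pd.DataFrame,
) -> np.ndarray:
    """Shift flank / body levels per the gene's planted expression class.

    Gene gaps are at least twice the 2 kb flank, so the flank/body intervals
    of distinct genes never overlap and a site maps to at most one interval.
    """
    deltas = linkage.set_index("gene_id")
    level = level.copy()
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for g in annotation:
        if g.gene_id not in deltas.index:
            continue
        fd = float(deltas.loc[g.gene_id, "flank_delta"])
        bd = float(deltas.loc[g.gene_id, "body_delta"])
        ivs = by_chrom.setdefault(g.chrom, [])
        ivs.append((g.start - 2000, g.start, fd))
        ivs.append((g.start, g.end, bd))
        ivs.append((g.end, g.end + 2000, fd))
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([iv[0] for iv in ivs])
        ends = np.array([iv[1] for iv in ivs])
        dvals = np.array([iv[2] for iv in ivs])
        mask = chroms == chrom
        p = pos[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        inside = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        add = np.zeros(len(p))
        add[inside] = dvals[idx[inside]]
        level[mask] += add
    return level


def simulate_linkage(
    config: SimulationConfig, annotation: list[GeneModel], fpkm: pd.Series
) -> pd.DataFrame:
    """Methylome adjustment coupling methylation to expression class.

    Returns one row per gene: expression_class, flank_delta (negative slope
    with class by default) and body_delta (positive slope).  Feed the frame
    to :func:`simulate_methylome` via ``linkage=``.
    """
    from .expression import expression_class

    classes = expression_class(fpkm.reindex([g.gene_id for g in annotation]).fillna(0.0))
    rank = classes.map({"none": 0, "low": 1, "middle": 2, "high": 3})
    return pd.DataFrame(
        {
            "gene_id": classes.index,
            "expression_class": classes.to_numpy(),
            "flank_delta": (rank * config.linkage_flank_step).to_numpy(dtype=float),
            "body_delta": (rank * config.linkage_body_step).to_numpy(dtype=float),
        }
    )


# ------------------------------------------------------------------- expression


@dataclass
class SimulatedExpression:
    """Counts, true FPKM, metadata and the planted ground truth."""

    counts: pd.DataFrame  # genes x samples, integer
    fpkm: pd.DataFrame  # genes x samples, noiseless 2**log2-expression
    gene_lengths: pd.Series
    total_mapped: pd.Series
    samples: pd.DataFrame  # sample, group, tissue, replicate
    traits: pd.DataFrame  # sample x (length, weight)
    module_labels: pd.Series  # gene -> planted module ("unassigned" for background)
    factors: pd.DataFrame  # module x sample latent factors
    de_genes: pd.DataFrame  # gene_id, log2fc (planted, de_group vs rest)


def simulate_expression(
    config: SimulationConfig, annotation: list[GeneModel]
) -> SimulatedExpression:
    """Expression matrix with planted modules, traits and DE genes.

    Module member genes follow x = base + scale * (sqrt(r) f_m + sqrt(1-r) e),
    which makes the within-module gene-gene correlation r; the first planted
    module's factor tracks the growth latent positively, the second
    negatively, further modules are trait-neutral.  Planted DE genes get a
    group-specific log2 shift.  Counts are negative-binomial around
    FPKM-implied means.
    """
    if sum(config.module_sizes) > config.n_genes:
        raise ValueError("module sizes exceed the number of genes")
    gene_ids = [g.gene_id for g in annotation]
    lengths = pd.Series({g.gene_id: g.length_bp for g in annotation}, name="length_bp")
    samples = []
    for group in config.groups:
        for tissue in config.tissues:
            for rep in range(1, config.replicates + 1):
                samples.append(
                    (f"{group}{_TISSUE_LETTER.get(tissue, tissue[0].upper())}{rep}", group, tissue, rep)
                )
    meta = pd.DataFrame(samples, columns=["sample", "group", "tissue", "replicate"])
    sample_ids = meta["sample"].tolist()
    n_s = len(sample_ids)

    rng_t = np.random.default_rng([config.seed, _S_TRAITS])
    growth = rng_t.normal(size=n_s)
    weight = 0.95 * growth + np.sqrt(1 - 0.95**2) * rng_t.normal(size=n_s)
    traits = pd.DataFrame({"length": growth, "weight": weight}, index=sample_ids)

    rng = np.random.default_rng([config.seed, _S_EXPR])
    factors = []
    for i in range(len(config.module_sizes)):
        c = config.trait_coupling[i] if i < len(config.trait_coupling) else 0.0
        factors.append(c * growth + np.sqrt(1 - c**2) * rng.normal(size=n_s))
    factors = pd.DataFrame(
        factors, index=[f"planted{i + 1}" for i in range(len(config.module_sizes))],
        columns=sample_ids,
    )

    labels = pd.Series("unassigned", index=gene_ids, name="module")
    offset = 0
    for i, size in enumerate(config.module_sizes):
        labels.iloc[offset : offset + size] = f"planted{i + 1}"
        offset += size

    base = rng.uniform(*config.base_log2fpkm, size=len(gene_ids))
    background = [g for g in gene_ids if labels[g] == "unassigned"]
    pool = background if len(background) >= config.n_planted_de else gene_ids
    de_ids = pool[: config.n_planted_de]
    for gid in de_ids:
        base[gene_ids.index(gid)] = rng.uniform(*config.de_base_log2fpkm)

    r = config.intra_cor
    x = np.empty((len(gene_ids), n_s))
    noise = rng.normal(size=x.shape)
    for gi, gene in enumerate(gene_ids):
        mod = labels.iloc[gi]
        if mod == "unassigned":
            x[gi] = base[gi] + config.background_noise_sd * noise[gi]
        else:
            f = factors.loc[mod].to_numpy()
            x[gi] = base[gi] + config.module_scale * (
                np.sqrt(r) * f + np.sqrt(1 - r) * noise[gi]
            )

    signs = np.where(np.arange(len(de_ids)) % 2 == 0, 1.0, -1.0)
    de = pd.DataFrame({"gene_id": de_ids, "log2fc": signs * config.de_log2fc})
    in_group = meta["group"].to_numpy() == config.de_group
    for gid, lfc in zip(de["gene_id"], de["log2fc"]):
        gi = gene_ids.index(gid)
        x[gi, in_group] += lfc

    fpkm = pd.DataFrame(2.0**x, index=gene_ids, columns=sample_ids)
    totals = pd.Series(config.total_mapped, index=sample_ids, name="total_mapped")
    mean_counts = fpkm.to_numpy() * lengths.to_numpy()[:, None] * config.total_mapped / 1e9
    size = 1.0 / config.count_dispersion
    p = size / (size + np.maximum(mean_counts, 1e-12))
    counts = pd.DataFrame(
        rng.negative_binomial(size, p), index=gene_ids, columns=sample_ids
    )
    return SimulatedExpression(
        counts=counts, fpkm=fpkm, gene_lengths=lengths, total_mapped=totals,
        samples=meta, traits=traits, module_labels=labels, factors=factors, de_genes=de,
    )
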