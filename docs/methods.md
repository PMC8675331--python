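# Methods

`methylink` re-implements, as a tested library, an integration analysis
between whole-genome bisulfite sequencing (WGBS) methylomes and RNA-seq
transcriptomes across multiple sample groups — the design of a three-group
(female / male / pseudomale) study of sexually dimorphic growth in a
flatfish, where DNA methylation differences are linked to expression
differences gene by gene.  This note records the models, the parameter
choices, and the places where the design was genuinely open.

## Coordinates and gene regions

All coordinates are 0-based half-open; BED is read natively and GFF3
(1-based inclusive) is converted on read, so a single convention holds
everywhere.  Each gene contributes three strand-aware analysis regions:
a 2 kb upstream flank, the gene body, and a 2 kb downstream flank, with
flanks clipped at chromosome bounds.  Upstream of a minus-strand gene lies
at higher coordinates.  The flank length (2 kb) is the conventional promoter
/ terminator proximity scale and is configurable.  Finer genomic features
(UTRs, exons, introns) are deliberately out of scope: the integration
operates on the three-region scheme only.

## Methylation levels

Per-cytosine input is a table of (chrom, pos, strand, context, methylated
count, total count), contexts CG / CHG / CHH.  The methylation level of any
site set is the *percentage of methylated cytosines*, i.e. the
coverage-weighted ratio Σ methylated / Σ total over sites with depth at
least `min_coverage` (default 4, one coherent coverage rule shared with DMR
calling).  The unweighted mean of per-site ratios is available behind a
flag but is not the default, because it over-weights shallow sites.  A
summary over zero covered sites is flagged undefined, never reported as 0.
Symmetric CpG counts are kept per strand as given; collapsing strands is
the caller's choice before input.

Methylated-cytosine calling tests each site's methylated count against the
bisulfite non-conversion error rate with a one-sided binomial upper tail,
P(X ≥ m | n, ε), ε defaulting to 0.01 (bisulfite conversion is typically
>99% efficient; the rate is a parameter, not estimated from spike-ins).
Calling algorithms vary between WGBS pipelines; the binomial formulation
is the standard, documented choice here, isolated behind one function.  Multiple testing uses Benjamini–Hochberg across all tested sites
of a sample.

Metagene profiles average, per bin, the per-gene coverage-weighted levels
over three zones: fixed-width bins across each flank and proportional-
position bins across the body (so short genes still contribute), oriented
so upstream bin 0 is farthest from the TSS.  Default 20/20/20 bins — the
bin count is presentation resolution, not an inference parameter.

## DMR calling

The genome is tiled into non-overlapping 200 bp windows anchored at
coordinate 0.  A window's test, per context, pools counts over sites
covered ≥ 4× in *both* groups and compares the two pooled (methylated,
unmethylated) pairs with a two-sided exact test; the methylation difference
is pooled level of group 1 minus group 2, ordered by the comparison name
("M-vs-F" means M − F).  Windowed DMR callers differ in their internal test; with one pooled library per group, a
2×2 conditional exact test is the minimal defensible choice, and the test
sits behind a single function should a regression alternative be wanted.
Windows are emitted only when they meet the context's site-count floor;
BH correction runs per context (the per-context acceptance rules imply
per-context testing families).  The acceptance triplets (min sites,
min |diff|, max q) are CG/CHG (5, 0.25, 0.05), CHH (15, 0.15, 0.05) and
all-contexts (20, 0.20, 0.05).

The exact test is computed vectorized from log-gamma binomial coefficients
over each table's full support, with the standard tie convention (all
outcomes with probability ≤ observed × (1 + 1e-7) are summed) and the total
normalized by the summed support mass.  This reproduces
`scipy.stats.fisher_exact` to ~1e-13 relative while testing tens of
thousands of windows in milliseconds.

A gene is differentially methylated (DMG) when at least one DMR overlaps
(half-open interval overlap, 1 bp suffices) any of its three regions.  The
reported region-level difference is the coverage-weighted level difference
over the whole region, in percentage points — the same quantity as the DMR
ratio and the quadrant threshold, in ×100 units.

## Differential expression

FPKM = count × 10⁹ / (gene length in bp × total mapped fragments).  The
DE stage is a deliberately simple stand-in for an external count-model
package: Welch's t on log2(FPKM + 1) per gene with BH across genes.  What
the pipeline consumes downstream is only the DEG filter — |log2FC| > 1 and
q < 0.05, both strict as printed — and the per-gene log2 fold changes
(group 1 over group 2 with pseudocount 1 on the FPKM scale).  The stage is
pluggable: any per-gene (log2FC, q) table can feed the integration.  With
fewer than two replicates in a group it degrades to fold-change-only with
an explicit warning.  Expression classes are none (FPKM ≤ 1), low (1, 10],
middle (10, 100], high (> 100).

## Co-expression modules

The weighted-network construction is the standard recipe: unsigned
soft-threshold adjacency a_ij = |cor(x_i, x_j)|⁸ (power 8; signed mode
available), topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij) with self
excluded from connectivities and shared-neighbour sums, average-linkage
clustering of 1 − TOM, and a minimum module size of 50 with smaller
clusters unassigned.

Instead of a dynamic tree cut, the tree is cut at a *static* height
(default 0.96).  The simplification is deliberate — only power and minimum
module size are prescribed — and the default is placed where the two height
populations separate: with power 8, within-module joins complete below
~0.95 across simulated module structures, while merges between distinct
modules approach 1 (the nearest observed cross-module merge in development
simulations was ~0.985).  A cut much lower (e.g. 0.25) would leave every
gene unassigned, because 1 − TOM dissimilarities concentrate near 1 even
inside strong modules.

A module eigengene is the first principal component of the module's
per-gene z-scored expression, sign-oriented to correlate non-negatively
with the module's mean profile.  Module–trait relations use Pearson
correlation of eigengenes with traits (two-sided t-based p); the
most-positive and most-negative modules per trait are flagged.  Gene
significance (GS) is the *signed* gene–trait correlation — a
negative hub threshold such as GS < −0.35 forces a signed definition.  Module
membership (MM) is the gene's correlation with its own eigengene, and
"weight" between two genes is their TOM entry, the quantity thresholded
for hub-network edges.  Hub genes satisfy the joint GS and MM constraints
(e.g. GS.length and GS.weight > 0.50 with MM > 0.90 for a positively
coupled module; GS < −0.35, MM > 0.90 for a negative one) and edges are
kept strictly above the weight floor; the maximal-degree gene is the top
hub.  TOM magnitudes scale with network size and density, so the weight
floor is genuinely data-dependent: genome-scale reference values
(0.60 / 0.48) are defaults, not constants of nature.

## Integration

Within a sample, genes are binned by expression class and a metagene
profile is computed per class; Spearman rank correlation (midranks for
ties, two-sided p) relates per-gene region methylation to expression
across genes, per region kind.  Between groups, the DEG set is intersected
with the DMG set, and each (gene, region) is classified on a 3×3 grid:
methylation class hypo / no-change / hyper at |meth.diff| > 25 percentage
points crossed with expression class up / no-change / down at |log2FC| > 1,
both strict, numbered row-major from quadrant 1 = (up, hypo) through 5 =
centre to 9 = (down, hyper).  The numbering is anchored by the two
conventionally named cells (quadrant 1 upper-left = up-regulated and hypomethylated;
quadrant 7 = down-regulated and hypomethylated, taken as the lower-left
cell — the one figure legend calling it "upper down" is read as a typo for
the lower row, consistent with the sign logic).

## Gene-set enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for k query hits in a term of size K against a universe of N
genes with a query of size n, BH-corrected per submitted collection, with
significance at FDR < 0.05.  The universe defaults to all genes annotated
in the collection ("genome background") and is overridable.  Gene sets are
user input in GMT form; ontology structure (DAG propagation, pathway
topology) is out of scope.

## Synthetic data

The generator emulates the statistical design of the study, not its
sequences: no reads, no alignment — per-cytosine counts and per-gene
expression directly.

Genome and annotation: two autosomes plus chrZ and chrW, 600 kb each, with
300 non-overlapping genes of 1–3 kb separated by ≥ 4 kb gaps (twice the
flank, so derived regions never collide).  The chromosome length is sized
so the default gene count packs with room to spare; the four-chromosome
layout keeps a sex-chromosome pair available for the planted bias.

Methylome: cytosine sites are placed uniformly at per-context densities
(CG 0.04/bp, CHG 0.03/bp, CHH 0.08/bp — chosen so a 200 bp window holds
~8 CG and ~16 CHH sites, comfortably above the per-context site floors).
A site's true level is the context baseline (CG 0.75, CHG 0.10, CHH 0.05)
plus a chromosome offset (chr2 −0.03), plus a +0.10 chrW offset for the
pseudomale group only (the planted sex-chromosome hypermethylation), plus
a CG body gradient of ±0.10 (high at body start, low at end), plus planted
DMR effects, plus site-level jitter (SD 0.03) shared across groups so null
windows are exactly null.  Read depth is negative-binomial (mean 30,
size 10, i.e. SD ≈ 11) and methylated counts are binomial at the site's
level.  Site layout is common to all groups; only counts differ.

Planted DMRs: 50 windows aligned to the 200 bp grid, drawn only among
windows whose site layout meets the context's site-count floor (an
untestable plant would not be a recovery experiment), default effect −0.4
on CG in the male group.

Expression: 3 groups × tissues × 3 replicates (two tissues by default; four
for the 36-sample module-recovery conditions).  Three planted modules of
100/100/80 genes follow x = base + 2.0·(√r·f_m + √(1−r)·ε) in log2-FPKM
units with intra-correlation r = 0.8; module factors couple to a growth
latent at +0.9 (module 1), −0.45 (module 2) and 0 (module 3).  Opposite
*strong* couplings to one trait would correlate the two modules themselves
(cor ≈ −0.81) and blur their boundary in an unsigned network, so the
negative coupling is moderate.  Traits are length and a weight at 0.95
correlation with it.  Twelve planted DE genes (background genes with
expressed baselines, log2 shifts ±4 in the male group) and negative-
binomial counts (dispersion 0.05) around FPKM-implied means complete the
matrix.  Baseline log2-FPKM is uniform on (−2, 9), spanning all four
expression classes.

Linkage plant: per expression class c ∈ {0..3}, flank levels shift by
−0.08·c and body levels by +0.05·c, equally in all groups, producing the
negative-flank / positive-body methylation–expression correlation at the
region scale.  Shifts that leave [0, 1] are clamped with a warning.

Everything is a pure function of (config, seed): independent
`default_rng([seed, stream])` streams drive annotation, site layout, DMR
placement, expression, traits and per-group counts.

What the generator does *not* emulate — and hence what passing recovery
tests do not establish about real data: linkage disequilibrium of
methylation between neighbouring sites (sites are independent given the
mean surface), replicate-level biological variance in methylomes (one
pooled library per group, as in the emulated design), batch effects,
annotation errors, and context-specific biology beyond level offsets.
Recovery results on this generator validate the machinery, not field
performance.

## Numerical choices and degenerate inputs

- Exact-test ties use the (1 + 1e-7) relative slack convention and the
  support-mass normalization described above; a full-support selection
  returns exactly 1.
- BH is always computed within the testing family stated for the stage
  (per context for windows, across genes for DE, per collection for
  enrichment, across tested sites for calling).
- Zero-coverage windows and all-constant modules raise or are skipped with
  a logged count — never silently zero.
- Undefined correlations (constant vectors, < 3 pairs) are NaN and
  flagged, not dropped silently.
- All output tables are written with stable sort orders so reruns are
  byte-identical.

## Problem sizes

Default experiment sizes (2.4 Mb genome, 360k cytosines per methylome,
300 genes, 18–36 samples, five seeds for recovery experiments) were chosen
so the full recovery suite and the acceptance script complete in a few
minutes on one CPU while every code path — all three contexts, all
window/site floors, clipping, clamping, unassigned genes — is exercised.

## Known limitations

- The DE stage is a two-sample test on transformed FPKM, not a count
  model; it is the documented, pluggable stand-in described above.
- DMR calling has no replicate-aware mode (the emulated design pooled
  replicates per methylome library) and adjacent significant windows are
  not merged.
- The static tree cut trades the adaptive behaviour of dynamic tree cut
  for transparency; modules of very unequal tightness may need a manual
  cut height.
- Enrichment treats terms independently; no term redundancy trimming.
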