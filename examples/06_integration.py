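"""Methylation-expression linkage and the nine-quadrant classification.

Within a sample: metagene profiles per expression class and Spearman rho
between region methylation and expression (flanks negative, body positive
on the planted data).  Between groups: DEG x DMG overlap and the 3x3
quadrant grid at |log2FC| > 1 and |meth.diff| > 25 percentage points.
"""

import methylink as ml
from methylink.genome import derive_all_regions

cfg = ml.SimulationConfig(seed=1)
genes = ml.simulate_annotation(cfg)
expr = ml.simulate_expression(cfg, genes)
fpkm_mean = expr.fpkm.mean(axis=1)

link = ml.simulate_linkage(cfg, genes, fpkm_mean)
rec_f = ml.simulate_methylome(cfg, genes, "F", linkage=link)
rec_m = ml.simulate_methylome(cfg, genes, "M", linkage=link)

regions = derive_all_regions(genes, 2000, cfg.chromosomes)
levels_f = ml.gene_region_levels(rec_f, regions)
rho = ml.spearman_linkage(levels_f, fpkm_mean)
print("Spearman methylation-expression rho per region (sample F):")
print(rho.round(4).to_string(index=False))

# between-group integration: per-gene log2FC x per-region meth.diff
meta = expr.samples
fpkm = ml.fpkm(expr.counts, expr.gene_lengths, expr.total_mapped)
de = ml.differential_expression(
    fpkm, meta.loc[meta["group"] == "M", "sample"].tolist(),
    meta.loc[meta["group"] == "F", "sample"].tolist(),
)
levels_m = ml.gene_region_levels(rec_m, regions)
md = levels_m.merge(levels_f, on=["gene_id", "region_kind"], suffixes=("_m", "_f"))
md["meth_diff"] = 100 * (md["level_m"] - md["level_f"])
quad = ml.quadrant_table(de, md[["gene_id", "region_kind", "meth_diff"]])
print("\nnine-quadrant counts (1 = up & hypo ... 5 = centre ... 9 = down & hyper):")
print(quad.groupby("quadrant").size().to_dict())

dmrs = ml.call_dmrs(ml.window_tests(rec_m, rec_f, "CG"), "CG")
dmgs = ml.annotate_dmgs(dmrs, regions)
ov = ml.overlap_deg_dmg(de, dmgs)
print(f"\nDEG x DMG: {ov.n_deg} DEGs, {ov.n_dmg} DMG rows, {ov.n_common} common "
      f"({ov.pct_of_degs:.1f}% of DEGs differentially methylated)")
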