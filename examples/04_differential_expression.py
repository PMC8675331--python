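"""FPKM, the DEG filter, expression classes and pathway coverage.

FPKM = count * 1e9 / (length_bp * total_mapped).  A gene is a DEG when
|log2FC| > 1 and BH-adjusted q < 0.05 (both strict).  Pathway coverage is
the percentage of a pathway's genes that are differentially expressed.
"""

import methylink as ml

cfg = ml.SimulationConfig(seed=1)
genes = ml.simulate_annotation(cfg)
expr = ml.simulate_expression(cfg, genes)
meta = expr.samples

fpkm = ml.fpkm(expr.counts, expr.gene_lengths, expr.total_mapped)
res = ml.differential_expression(
    fpkm,
    meta.loc[meta["group"] == "M", "sample"].tolist(),
    meta.loc[meta["group"] == "F", "sample"].tolist(),
)
called = set(res.loc[res["is_deg"], "gene_id"])
planted = set(expr.de_genes["gene_id"])
print(f"M-vs-F: {len(called)} DEGs of {len(res)} genes; "
      f"{len(called & planted)}/{len(planted)} planted DE genes recovered")

classes = ml.expression_class(fpkm.iloc[:, 0])
print("expression classes in sample", fpkm.columns[0], ":",
      classes.value_counts().to_dict())

# worked example: 104 of the cell cycle's 145 genes differentially expressed
print(f"pathway coverage(104, 145) = {ml.pathway_coverage(104, 145)}%")
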