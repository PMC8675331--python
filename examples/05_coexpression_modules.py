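"""Weighted co-expression modules, trait correlation, and hub genes.

Adjacency |cor|^8, topological overlap, average-linkage clustering of
1 - TOM with a minimum module size of 50.  Gene significance (GS) is the
gene-trait correlation, module membership (MM) the gene-eigengene
correlation, and "weight" the TOM entry between two genes; hubs satisfy
joint GS / MM thresholds and keep edges above the weight floor.
"""

import numpy as np

import methylink as ml

cfg = ml.SimulationConfig(seed=1, tissues=("gonad", "muscle", "brain", "liver"))
genes = ml.simulate_annotation(cfg)
expr = ml.simulate_expression(cfg, genes)

res = ml.build_network(np.log2(expr.fpkm), expr.traits)
print("module sizes:", res.labels.value_counts().to_dict())
print("module-trait correlations:")
print(res.module_trait_r.round(3).to_string())
most_pos, most_neg = ml.network.flag_extreme_modules(res.module_trait_r, "length")
print(f"most positive: {most_pos}, most negative: {most_neg}")

# Edge weights are TOM values, whose magnitude depends on network size and
# density: a genome-scale network supports a floor like 0.60, which this 300-gene
# example rarely reaches, so the floor is set at the 90th percentile of the
# module's weights to show the edge machinery.
module_genes = res.labels.index[res.labels == most_pos]
w = res.tom.loc[module_genes, module_genes].to_numpy()
floor = float(np.quantile(w[np.triu_indices_from(w, 1)], 0.90))
hubs, edges, top = ml.select_hub_genes(
    res, most_pos, ml.HubCriteria(0.50, "above", 0.90, floor)
)
print(f"\n{len(hubs)} hub genes in {most_pos} "
      f"(GS.length & GS.weight > 0.50, MM > 0.90), "
      f"{len(edges)} edges with weight > {floor:.3f}")
print("top hub (max degree):", top)
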