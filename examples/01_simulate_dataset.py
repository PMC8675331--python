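"""Generate a synthetic three-sex-group methylome + transcriptome dataset.

The generator plants known structure (DMR windows, DE genes, co-expression
modules coupled to growth traits, a chrW methylation bias) so every later
pipeline stage can be checked against ground truth.
"""

import methylink as ml

cfg = ml.SimulationConfig(seed=1)
genes = ml.simulate_annotation(cfg)
expr = ml.simulate_expression(cfg, genes)
meth_f = ml.simulate_methylome(cfg, genes, "F")

print(f"genome: {len(cfg.chromosomes)} chromosomes, "
      f"{sum(cfg.chromosomes.values()) / 1e6:.1f} Mb, {len(genes)} genes")
print(f"methylome (group F): {len(meth_f):,} cytosine sites, "
      f"mean depth {meth_f['count_total'].mean():.1f}x")
print(f"expression: {expr.counts.shape[0]} genes x {expr.counts.shape[1]} samples "
      f"({'/'.join(cfg.groups)} x {'/'.join(cfg.tissues)} x {cfg.replicates} reps)")
print(f"planted: {cfg.n_planted_dmrs} CG DMR windows (effect {cfg.dmr_effect:+.1f}), "
      f"{len(expr.de_genes)} DE genes (|log2FC| {cfg.de_log2fc}), "
      f"modules of sizes {cfg.module_sizes}")
# Same seed -> byte-identical output; different groups share the site layout
# but draw their own read counts.
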