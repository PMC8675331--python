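"""Windowed DMR calling between two groups and DMG annotation.

200 bp tiles, sites covered >= 4x in both groups, two-sided exact test on
pooled counts, BH per context, then the CG acceptance rule: >= 5 sites,
|diff| >= 0.25, q <= 0.05.  DMRs overlapping a gene's upstream-2k, body or
downstream-2k region make that gene a DMG.
"""

import methylink as ml
from methylink.genome import derive_all_regions

cfg = ml.SimulationConfig(seed=1)
genes = ml.simulate_annotation(cfg)
g_m = ml.simulate_methylome(cfg, genes, "M")
g_f = ml.simulate_methylome(cfg, genes, "F")

tests = ml.window_tests(g_m, g_f, "CG")          # M-vs-F: diff = level_M - level_F
dmrs = ml.call_dmrs(tests, "CG")
planted = {(d.chrom, d.start) for d in ml.plant_dmrs(cfg)}
hit = set(zip(dmrs["chrom"], dmrs["start"]))

print(f"{len(tests)} CG windows tested, {len(dmrs)} DMRs called")
print(f"planted {len(planted)}, recovered {len(planted & hit)}, "
      f"false calls {len(hit - planted)}")
print(dmrs.head(3).round(4).to_string(index=False))

regions = derive_all_regions(genes, 2000, cfg.chromosomes)
dmgs = ml.annotate_dmgs(dmrs, regions, g_m, g_f)
print(f"\n{dmgs['gene_id'].nunique()} DMGs; region_diff is the M-F difference "
      "over the whole region, in percentage points:")
print(dmgs.head(3).to_string(index=False))
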