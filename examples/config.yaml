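# Example pipeline configuration for the `methylink` CLI.
# Every key is optional; defaults are the standard analysis thresholds.
# CLI flags override file values; the resolved config is logged per run.

seed: 1

# coordinates / windows
flank_bp: 2000        # upstream/downstream analysis flank
window_bp: 200        # DMR calling window (non-overlapping tiles)
min_coverage: 4       # per-site read depth floor, per group

# methylated-cytosine calling
error_rate: 0.01      # bisulfite non-conversion rate (treatment > 99% efficient)
call_alpha: 0.05

# per-context DMR acceptance: [min sites in window, min |diff|, max q]
dmr_thresholds:
  CG:   [5, 0.25, 0.05]
  CHG:  [5, 0.25, 0.05]
  CHH:  [15, 0.15, 0.05]
  allC: [20, 0.20, 0.05]

# differential expression
fc_threshold: 1.0     # DEG needs |log2FC| > 1 (strict)
q_threshold: 0.05     # ... and q < 0.05 (strict)
pseudocount: 1.0      # on the FPKM scale

# integration
md_threshold: 25.0    # |meth.diff| > 25 percentage points for hypo/hyper

# co-expression network
power: 8
min_module_size: 50
cut_height: 0.96      # static cut on the 1-TOM dendrogram

# metagene profile
n_bins_flank: 20
n_bins_body: 20

enrich_q: 0.05
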