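# Reference-cohort run: generator calibrated to the published cohort
# distributions and regression structure (n scaled down for a quick run).
mode: simulate
preset: maastricht_table1
n: 500
seed: 0
default_sparsity: 0.80
n_null: 100
swaps_per_edge: 10.0
alpha: 0.05
change_threshold: 0.10
motion_exclusion_mm: 1.0
outdir: connqc_run
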