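# Null generator: quality metrics are pure noise (no covariate dependence),
# all participants share the base connectome template.
mode: simulate
preset: "null"
n: 200
seed: 0
default_sparsity: 0.80
n_null: 50
swaps_per_edge: 10.0
alpha: 0.05
change_threshold: 0.10
motion_exclusion_mm: 1.0
outdir: connqc_null_run
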