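# Demo run: one simulated three-city campaign, mass outcome, city-specific
# and pooled models, coarse prediction grids.  Completes in a few minutes.
seed: 5
schema: compact
n_sites: 40
repeat_fraction: 0.3333333333333333
scopes: [city, pooled]
outcomes: [coarse]
k_folds: 10
urban_spacing_m: 500.0
rural_spacing_m: 2000.0
outdir: results/demo
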