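# Example configuration for `masslmm run-all --config docs/example-config.yaml`.
# Omitted keys take the defaults documented in masslmm.pipeline.RunConfig.
n_sets: 36
n_participants: 12
seed: 0
preset: syntactic-complexity
rois: [LPTL, LATL, LIFC, LAG]
effect_roi: LPTL
effect_window: [0.850, 0.970]
effect_amplitude: 0.45
n_perm: 200          # raise to 10000 for publication-grade permutation p-values
alpha: 0.05
adjust: tukey
spectral_n_perm: 500
beta_freq: 18.0
beta_window: [0.780, 1.180]
beta_amplitude: 0.35
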