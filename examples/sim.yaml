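# Full pipeline on a synthetic experiment at the reference conditions.
simulation:
  n_genes: 1000
  genome_length: 6000000
  suppression_s: 0.5
  retention_boost_r: 1.6
  subset_fraction: 0.1
  expression_coupling_rho: 0.8
  seed: 1
processing:
  window_bp: 100
  threshold_quantile: 95
  normalize: true
stats:
  n_iter: 100000
  seed: 1
  tolerance: 0.05
  fdr_level: 0.05
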