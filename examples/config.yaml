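synthetic:
  n_genes: 500
  n_edges: 2500
  n_sites: 12
  samples_per_site: 30
  n_dnm_genes: 25
  n_cv_genes: 40
  n_overlap: 5
  coexpr_strength: 0.8
  unexpressed_fraction: 0.2
  rng_seed: 42
thresholds:
  n_perm: 1000
  n_baseline: 20
rng_seed: 42
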