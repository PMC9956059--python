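# Bundled demo: a small synthetic cross run end to end.
seed: 20230214
outdir: crossscreen_demo
sim:
  n_sites: 1500
  n_candidate_sites: 40
  samples_per_group: 5
  genotype_error_rate: 0.0
  missing_rate: 0.0
  n_chromosomes: 3
  cds_fraction: 0.3
policy:
  require_segregation: true
  max_founder_missing: 0
enrichment:
  n_terms: 8
  n_extra_genes: 40
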