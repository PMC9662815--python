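# Demo configuration for `hybridcre run --config examples/demo_config.yaml`.
# Generates a small synthetic diploid fixture and runs every stage.
output_dir: hybridcre_demo_out
seed: 7
log_level: INFO

synthetic:
  n_loci: 120
  locus_length: 2000
  gc_fraction: 0.42
  snp_rate: 0.00714      # wild-derived preset, ~1 variant per 120 bp combined
  indel_rate: 0.00118
  disruption_prob: 0.5
  depth_mean: 100
  dispersion: 1e9        # Poisson-limit counts; the default skew test is exact here
  n_replicates: 2
  motif_specs:
    - {pattern_id: AP1, pattern: VTGACTCAB, prob: 0.5, max_offset: 50}
    - {pattern_id: TEAD, pattern: GGAATK, prob: 0.5, max_offset: 50}

catalog:
  mappability_halfwidth: 60
  central_width: 150
  dedup_distance: 1000
  quintile_floor: 0.2
  imprint_margin: 100000
  proximal_threshold: 1000

skew:
  fdr_threshold: 0.1
  fold_thresholds: [2, 4]
  tf_halfwidth: 250
  histone_halfwidth: 500
  pseudocount: 1
  test: binomial
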