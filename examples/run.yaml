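# Example pipeline configuration for `divscan run --config examples/run.yaml`.
# Any omitted key falls back to the package default; unknown keys are rejected
# before any stage runs.
seed: 11

simulate:
  n_founders: 150
  n_snp: 600
  n_chrom: 3
  n_qtl: 30
  h2: [0.45, 0.45]
  rg: 0.54
  generations: 6
  n_offspring: 100
  final_males: 253
  final_females: 305
  n_genotyped_sires: 20
  n_g0_genotyped_sires: 40
  big_qtl_variance: 0.12

qc:
  maf_min: 0.05
  snp_callrate_min: 0.95
  ind_callrate_min: 0.95

flk:
  fdr: 0.05
  merge_distance: 1000000

hapflk:
  K: 5
  n_em_runs: 2
  max_iter: 40
  fdr: 0.05

trajtest:
  n_sims: 100000
  top_n: 3

bayescpi:
  n_iter: 12000
  burn_in: 2400
  thin: 12
  bf_threshold: 20.0
  flank: 1000000

posthoc:
  ld_max_distance: 500000
  ld_maf_min: 0.1
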