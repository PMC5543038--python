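# Demo pipeline configuration: small enough to run end to end in about a
# minute.  All SimulationConfig, QcThresholds and analysis fields can be
# set here; unset fields keep their defaults.
seed: 7
outdir: pipeline_out
simulate:
  n_founders: 200
  n_generations: 2
  offspring_per_pair: 2
  n_snps: 300
  n_chromosomes: 2
  ld_decay_bp: 2000.0
  maf_range: [0.15, 0.45]
  n_years: 9
  mean_records: 1.5
  v_a: 10.8
  v_pe: 3.0
  v_res:
    cold: 15.4
    intermediate: 14.5
    warm: 11.9
qc:
  min_call_rate: 0.95
  min_maf: 0.10
  het_fdr: 0.01
  max_ibs: 0.95
  min_class_count: 5   # desk-scale stand-in for the published 20
analysis:
  residuals: heterogeneous
  vc_mode: null-fixed
  alpha: 0.05
  keff_window: 20
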