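# Full pipeline demonstration on a medium-sized synthetic study.
outdir: prs_run
seed: 11
simulation:
  n_snps: 313
  n_low_info: 26
  n_cases: 4000
  n_controls: 4000
  n_prospective: 5000
  n_strata: 5
  baseline_hazard: 0.003
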