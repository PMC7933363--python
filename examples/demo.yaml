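# Small demonstration cohort: two simulated SV callers over planted truth
# deletions, run end-to-end with `delscan run-all --config examples/demo.yaml`.
seed: 7
params:
  ro_threshold: 0.5
  min_len: 500
  max_len: 100000
  flank: 1000
  af_threshold: 0.05
  alpha: 0.05
  primary_caller: manta
simulate:
  n_truth_deletions: 120
  n_genes: 150
  chrom_sizes: {chr1: 6000000, chr2: 6000000}
  populations: {Pachon: 8, Tinaja: 8, RioChoy: 8}
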