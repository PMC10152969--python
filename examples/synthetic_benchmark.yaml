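# Full benchmark run on synthetic planted-motif data.
outdir: scratch/synthetic_benchmark
seed: 7
simulate:
  n_peptides: 20
  n_records: 1200
  zipf_exponent: 0.5
  motif_strength: 1.0
build:
  variant: base
split:
  method: uniform
  k: 5
evaluate:
  predictor: kmer_nn_calibrated
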