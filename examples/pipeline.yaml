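# Full-pipeline configuration: a small demonstration cohort.
seed: 7
cohort:
  n_hd: 10
  n_control: 10
  noise_sd: 1.0
model:
  form: dynamic
stages:
  model_comparison: false
  connectivity: false
  bma: true
  summaries: true
  loo: true
output_dir: results/demo
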