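# Demo pipeline configuration: two-region synthetic world, driver search,
# mosaic, and sensitivity analysis. Run with
#   emberfire run --config examples/demo.yaml
out_dir: demo
seed: 7
world:
  n_lat: 20
  n_lon: 20
  resolution: 3.0
  years: 14
  start_year: 2002
  regions:
    - [SA, [0, 20], [0, 10]]
    - [NHAF, [0, 20], [10, 20]]
  noise_sd: 0.3
  zero_inflation: 0.3
niche:
  kappa: {NHAF: 0.15, SA: 1.2}
candidates: [ts, pr, gppl1, cld, vp, pop]
train:
  max_epochs: 60
  patience: 15
weights:
  w_IA: 4
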