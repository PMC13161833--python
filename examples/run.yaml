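# Example configuration for the kgflux CLI workflow.
#
#   kgflux simulate  --config examples/run.yaml --out run/
#   kgflux train     --config examples/run.yaml --out run/
#   kgflux partition --config examples/run.yaml --out run/
#   kgflux evaluate  --config examples/run.yaml --out run/
#   kgflux ablate    --config examples/run.yaml --out run/ --terms nee,night
#
# Any omitted key keeps its library default; --seed on the command line
# overrides the seed below.

seed: 1

site:
  n_days: 120          # one growing season; use 365 for a full site-year
  start_doy: 90
  latitude_deg: 43.0
  kok_max_suppression: 0.15

model:
  encoder_width: 128
  dropout_rate: 0.1
  mc_samples: 30

train:
  epochs: 60           # 150 for the full-scale runs
  patience: 15
  batch_size: 256
  learning_rate: 0.001

weights:
  nee: 1.0
  medlyn: 0.3
  night: 1.0
  pcea: 0.5
  rcea: 0.5
  wue: 0.05
  gs_t: 0.1
  base: 0.1

loss_options:
  norm: mad            # or mse
  medlyn_form: sqrt_vpd  # or vpd
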