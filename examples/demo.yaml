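synth:
  n_subjects: 6
  strides_per_subject: 30
  sample_rate: 100.0
  stride_duration_mean: 1.7
  stride_duration_sd: 0.03
  n_harmonics: 4
  amplitude_scales:
  - 3.0
  - 5.0
  - 150.0
  - 300.0
  subject_variation_sd: 0.1
  noise_sd:
  - 0.015
  - 0.025
  - 0.75
  - 1.5
  seed: 1
window:
  input_size: 25
  output_size: 5
forecaster:
  encoder_units: 32
  decoder_units: 32
  n_features: 4
  w_in: 25
  w_out: 5
  epochs: 20
  batch_windows: 100
  learning_rate: 0.001
  beta1: 0.9
  beta2: 0.999
  epsilon: 1.0e-07
  seed: 1
  activation: relu
  grad_clip: null
evaluation:
  n_test_strides: 1
  lowpass_cutoff: null
  run_sweep: false
  sweep_sizes:
  - 5
  - 10
  - 15
  - 20
  - 25
  - 30
  - 35
  - 40
  run_horizons: false
  horizons:
  - 5
  - 10
seed: 1
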