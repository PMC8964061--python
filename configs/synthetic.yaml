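neuron:
  u_rest: 0.0
  u_reset: 0.0
  u_th: 0.3
  tau_m: 9.4912
  dt: 1.0
  gain: 32.0
network:
  hidden_size: 256
  seed: 42
synth:
  n_classes: 4
  grid:
  - 16
  - 16
  duration_ms: 300
  base_rate: 2.0
  noise_rate: 0.001
  jitter_ms: 1.0
  samples_per_class: 100
  seed: 7
  bar_width: 2
  test_per_class: 50
binning:
  frames: 25
  time_mode: compress
train:
  learning_rate: 0.001
  epochs: 20
  batch_size: 64
  surrogate_width: 1.0
  seed: 11
  optimizer: adam
schedule:
  stim_ms: 25.0
  relax_ms: 25.0
  inh_weight: -0.05
  inh_step: null
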