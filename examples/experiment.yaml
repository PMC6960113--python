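# Example configuration for `netage run-all --config experiment.yaml`
# (also loadable with netage.load_config).  Omitted keys take defaults.
cohort:
  n_subjects: 380
  grid_dims: [20, 20, 20]
  n_networks: 7
  # per-network GMV-age correlation targets (FPN, DAN, DMN, SMN, VAN, VN, LN)
  target_r: [-0.78, -0.70, -0.74, -0.75, -0.75, -0.60, -0.57]
  age_low: 18
  age_high: 90
test_count: 80          # held-out subjects (~ the 151/1454 fraction)
methods: [GPR, RVR]     # add CNN for the three-method comparison
cnn:
  base_channels: 4
  n_stacks: 4
  fc_widths: [32, 16]
  epochs: 14
  learning_rate: 0.005
  lr_decay_every: 7
  restarts: 3
kernel:
  normalize_kernel: true
  gpr:
    center_kernel: true
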