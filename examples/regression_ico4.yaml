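# Small MS-SiT for ico4-resolution regression (desk-scale).
model:
  task: regression
  input_order: 4
  num_input_channels: 4
  base_dim: 16
  depths: [1, 1, 1, 1]
  heads: [2, 2, 2, 2]
  mlp_ratio: 2.0
train:
  epochs: 25
  batch_size: 16
  seed: 0
  lr_max: 0.001
  augmentation:
    max_rotation_deg: 30.0
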