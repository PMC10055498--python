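# Small U-shaped MS-SiT for 8-region parcellation at ico4 (desk-scale).
model:
  task: segmentation
  input_order: 4
  num_input_channels: 2
  base_dim: 16
  depths: [1, 1, 1, 1]
  heads: [2, 2, 2, 2]
  mlp_ratio: 2.0
  num_outputs: 8
train:
  epochs: 40
  batch_size: 8
  seed: 0
  lr_max: 0.003
  augmentation:
    max_rotation_deg: 15.0
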