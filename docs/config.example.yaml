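# Full-scale training configuration (the values the method was published
# with); pass to the CLI via --config or load with pipeline.load_config.
lr: 1.0e-4            # initial Adam learning rate (constant; no schedule)
batch_size_seg: 16
batch_size_class: 32
max_epochs: 100
loss:
  gamma: 0.02         # rank-loss weight in the hybrid loss
  k: 20               # hard pixels per region per image
  margin: 0.3         # required fg/bg probability gap
  epsilon: 1.0e-6     # Dice smoothing
backbone:
  width_multiplier: 1.0
  output_stride: 16
  dilation_rates: [6, 12, 18]
  middle_repeats: 16
classifier:
  input_channels: 4   # RGB patch + coarse probability map
  dilated_exit: true
seed: 0
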