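# Desk-scale pipeline configuration (~20 s on one CPU).
fast: true
n_desc_folds: 2
sim:
  n_subjects: 6
  n_images: 10
  rate_hz: 500.0
cnn: {base_channels: 8, epochs: 8, hidden: 64}
dual: {base_channels: 8, epochs: 8, hidden: 64}
descriptor: {base_channels: 8, epochs: 60}
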