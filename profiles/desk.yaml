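# Desk-scale profile: small inputs and a short schedule so a full
# train/validate cycle completes in minutes on one CPU.
network:
  input_size: [64, 128]   # (height, width)
training:
  epochs: 40
  batch_size: 8
  lr0: 0.01
data:
  synthetic: 32
  val_fraction: 0.2
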