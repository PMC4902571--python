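mode: tirf
seed: 7
out_dir: out
simulation:
  mixture: {1: 0.94, 2: 0.06}
  p_dark: 0.30
  n_spots: 2000
  n_frames: 500
  bleach_rate: 0.005
analysis:
  support: [1, 2]
  coloc_two_step: 0.03
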