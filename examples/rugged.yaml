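# Specialist phage on a rugged slope (smoothing window span = 5).
parameters:
  T: 2.0e6
  s: 1000
  M_B: 1.0e-5
  M_V: 1.0e-5
landscape:
  kind: rugged_slope
  span: 5
  seed: 7
  amplitude: 0.2
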