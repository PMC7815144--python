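# NCG scenario, square-wave supply with period T = 40 min (ON/OFF 20 min each).
environment:
  mode: ncg
  D: 5.0
  d: 1.0e-6
  schedule:
    kind: square_wave
    glc0_on: 2.0
    glc0_off: 0.01
    T_on: 20.0
simulation:
  N0: 10000
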