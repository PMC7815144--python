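# NCG scenario with constant 2 mM glucose supply.
environment:
  mode: ncg
  D: 5.0
  d: 1.0e-6
  schedule:
    kind: constant
    glc0_on: 2.0
simulation:
  N0: 10000
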