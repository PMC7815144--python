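# Chemostat with a glucose pulse train: 1 min pulses of 300 mM supply,
# variable OFF phases (mean 99 min, CV 5 %), dilution rate D = 4e-3 /min.
environment:
  mode: chemostat
  V_ch: 1.0e-8
  D: 4.0e-3
  schedule:
    kind: pulse_train
    glc0_on: 300.0
    glc0_off: 0.01
    T_on: 1.0
    T_off_mean: 99.0
    T_off_cv: 0.05
simulation:
  N0: 50000
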