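# Default expression-cost function: sum of fourth powers, unit weights.
cost:
  variant: power_sum
  n: 4
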