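# Alternative expression-cost function: fourth power of the weighted sum.
cost:
  variant: power_of_sum
  n: 4
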