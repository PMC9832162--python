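layers:
  - {family: poisson, params: {mean: 50}, T: 0.1}
  - {family: poisson, params: {mean: 2},  T: 0.6}
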