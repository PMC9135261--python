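# Shallow bimodal regime: both modes carry mass, relaxation time ~1.3e3
model:
  family: logit
  F: 0.025
  J: 1.5
  alpha: 0.0
  beta: 1.0
  gamma: 1.0
  N: 50
task:
  name: spectrum
seed: 1
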