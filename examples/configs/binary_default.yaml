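# Low-cohesion analytic regime: 5 competing populations, symmetric drive.
binary:
  n_pops: 5
  pop_size: 100
  beta: 2.0
  w_plus: 0.5
  w_inh: 0.5
  inputs: [1.0, 1.0, 1.0, 1.0, 1.0]
  bias: 0.1
  inhibit_within: true
  pair_scaling: true
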