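# Quarter-scale spiking network at the default inhibition level.
# Neuron and synapse sections are omitted: the published-table defaults apply.
architecture:
  n_excitatory: 800
  n_inhibitory: 200
  n_selective_pools: 2
  pool_size: 80
  w_plus: 1.9
  w_inh: 1.0
  n_external: 800
  external_rate: 3.0
protocol:
  stabilization_ms: 500.0
  stimulus_ms: 500.0
  stimulus_rate: 120.0
  bias_rate: 0.0
  noise_sigma: 50.0
  noise_tau: 10.0
dt: 0.05
scale: 0.25
seed: 1
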