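"""One trial of the conductance-based attractor network, reduced 4x.

Simulates 500 ms of background-only stabilization followed by 500 ms of
stimulation of both selective pools (plus a 20 Hz bias to pool 1), then
prints pool firing rates, the pool-1 synaptic current decomposition and its
distance from the threshold current, and writes the raster and current
trace as CSV.
"""

import numpy as np

from balanced_coding.spiking import (
    ArchitectureParams,
    StimulusProtocol,
    build_network,
    mean_current_vs_threshold,
    pool_spike_counts,
    save_currents_csv,
    save_rasters_csv,
    simulate_trial,
)

arch = ArchitectureParams(w_inh=1.0)
protocol = StimulusProtocol(stimulus_ms=500.0, stimulus_rate=40.0,
                            bias_rate=20.0)
network = build_network(arch, scale=0.25)
raster, record = simulate_trial(network, protocol, dt=0.05, seed=1)

window = (protocol.stabilization_ms, protocol.duration_ms)
names = ["pool 1 (biased)", "pool 2", "non-selective", "inhibitory"]
print(f"{network.n_neurons} neurons, stimulus window {window} ms:")
for p, name in enumerate(names):
    n = network.pool_sizes[p]
    rate = pool_spike_counts(raster, p, window).sum() / n / 0.5
    print(f"  {name:16s}: {rate:6.2f} Hz over {n} neurons")

sel = (record.time_ms >= window[0]) & (record.time_ms < window[1])
exc = record.excitatory[sel, 0].mean()
inh = record.inhibitory[sel, 0].mean()
bal = mean_current_vs_threshold(record, window_ms=window)
print(f"\npool-1 mean synaptic current: {exc:+.3f} nA excitatory, "
      f"{inh:+.3f} nA inhibitory")
print(f"threshold current           : {record.threshold_current:.3f} nA")
print(f"current balance             : {bal:+.3f} nA "
      f"({'supra' if bal > 0 else 'sub'}threshold mean drive)")

save_rasters_csv([raster], "raster_trial0.csv")
save_currents_csv(record, "currents_trial0.csv")
print("\nwrote raster_trial0.csv and currents_trial0.csv "
      "(columns: trial,neuron,time_ms,pool / time_ms,pool,mean_current_nA,...)")
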