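"""Reduced inhibition-level sweep of the spiking attractor network.

Sweeps the inhibitory-to-excitatory weight w_I across the current-balance
transition at 1/4 network scale, simulating trials at bias -10/0/+10 Hz per
grid point, and prints the pool-1 current balance, the empirical Fisher
information of the bias, and its slope^2/variance analytic fit.  Takes a few
minutes; enlarge n_trials / the grid for smoother curves (the acceptance
suite runs 200 trials on 7 points).
"""

import numpy as np

from balanced_coding.experiments import SweepSpec, run_moment_fit_sweep
from balanced_coding.spiking import ArchitectureParams, StimulusProtocol

arch = ArchitectureParams()
protocol = StimulusProtocol(stimulus_ms=500.0)
spec = SweepSpec(
    w_inh_grid=np.array([0.80, 0.95, 1.10, 1.25]),
    n_trials=60, scale=0.25, master_seed=1, dt=0.1, n_bootstrap=100,
)
result = run_moment_fit_sweep(arch, protocol, spec)

cols = ["w_inh", "current_balance_nA", "mean_count", "fisher_empirical",
        "fisher_se", "fisher_gaussian_form"]
print(result.table[cols].to_string(index=False,
                                   float_format=lambda x: f"{x:.4g}"))
print(f"\nzero crossing of (mean current - threshold): "
      f"w_I = {result.meta['zero_crossing_w_inh']:.3f}")
print(f"empirical Fisher information argmax:          "
      f"w_I = {result.meta['argmax_fisher_empirical']:.3f}")
print(f"analytic fit within 2 bootstrap SE at "
      f"{100 * result.meta['fit_within_band_fraction']:.0f}% of grid points")
print("""
The mean synaptic current of the biased pool crosses the threshold current
inside the swept range; the Fisher information of the bias peaks at the
grid point nearest that crossing — encoding sensitivity is maximal at the
excitation-inhibition balance — and the slope^2/variance form tracks the
empirical estimate.""")
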