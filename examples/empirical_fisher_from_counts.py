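"""Empirical Fisher information from a trial x count table.

Builds synthetic Poisson and Gaussian count families with known
sensitivity to a bias parameter, writes them to a delimited-text table (the
same format the estimator accepts for real recordings), and checks the
histogram / finite-difference estimator against the closed forms
slope^2/mean (Poisson) and slope^2/variance (Gaussian).
"""

import tempfile
from pathlib import Path

import numpy as np

from balanced_coding.estimator import (
    CountSample,
    fano_factor_counts,
    fisher_empirical,
    fisher_gaussian_form,
    fisher_poisson_form,
    load_count_table,
    save_count_table,
)

rng = np.random.default_rng(0)
slope, mu, sigma, delta, n_trials = 1.0, 300.0, 20.0, 10.0, 4000

# Poisson family: mean mu + slope*bias -> F = slope^2 / mu
poisson = [CountSample(rng.poisson(mu + slope * b, n_trials), bias_value=b)
           for b in (-delta, +delta)]
est = fisher_empirical(*poisson, n_bootstrap=100, seed=1)
truth = fisher_poisson_form(mu, slope)
print("Poisson counts  (mu=300, slope=1 count/Hz):")
print(f"  empirical F = {est.value:.3e} +- {est.standard_error:.1e} Hz^-2")
print(f"  closed form = {truth.value:.3e} Hz^-2 "
      f"({100 * abs(est.value / truth.value - 1):.1f}% off)")
print(f"  Fano factor at -delta = "
      f"{fano_factor_counts(poisson[0]):.3f} (Poisson -> 1)")

# Gaussian family round-tripped through the CSV interchange format
gauss = [CountSample(np.round(rng.normal(mu + slope * b, sigma, n_trials))
                     .astype(int), bias_value=b) for b in (-delta, +delta)]
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "counts.csv"
    save_count_table(gauss, path)
    loaded = load_count_table(path)
est = fisher_empirical(*loaded, n_bootstrap=100, seed=2)
truth = fisher_gaussian_form(slope, sigma ** 2)
print("\nGaussian counts (sigma=20, slope=1 count/Hz), via CSV round-trip:")
print(f"  empirical F = {est.value:.3e} +- {est.standard_error:.1e} Hz^-2")
print(f"  closed form = {truth.value:.3e} Hz^-2 "
      f"({100 * abs(est.value / truth.value - 1):.1f}% off)")
print("""
Both estimates sit within a few percent of their closed forms at 4000
trials per side; 1/F bounds the variance of any unbiased read-out of the
bias from these counts (Cramer-Rao).""")
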