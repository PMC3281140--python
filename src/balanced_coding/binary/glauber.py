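"""Asynchronous Glauber Monte-Carlo sampling of the binary network.

Random-scan single-neuron updates: each elementary update picks one neuron
uniformly at random and sets it active with the logistic probability of its
local field (self-coupling excluded).  One sweep = n_neurons updates.  For the
symmetric couplings used here the chain is ergodic with the Boltzmann-Gibbs
stationary distribution of :func:`~balanced_coding.binary.model.energy`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ..errors import InvalidParameterError
from .model import BinaryNetworkParams

__all__ = ["GlauberResult", "glauber_simulate"]


@dataclass(frozen=True)
class GlauberResult:
    """Per-sweep samples from a Glauber chain (burn-in removed).

    ``pop_counts``: (n_samples, n_pops) active counts per population;
    ``codes``: integer configuration codes (bit i = neuron i state), usable as
    a full-state histogram for systems of <= 63 neurons.
    """

    pop_counts: np.ndarray
    codes: np.ndarray
    params: BinaryNetworkParams
    n_sweeps: int
    burn_in: int
    seed: int

    @property
    def n_samples(self) -> int:
        return self.pop_counts.shape[0]

    def mean_activity(self) -> np.ndarray:
        """Empirical per-population mean activity (per neuron, in [0, 1])."""
        return self.pop_counts.mean(axis=0) / self.params.pop_size

    def state_distribution(self) -> np.ndarray:
        """Empirical probability of each of the 2**n configurations."""
        n = self.params.n_neurons
        if n > 20:
            raise InvalidParameterError(
                "full state distribution only supported for <= 20 neurons"
            )
        hist = np.bincount(self.codes, minlength=2 ** n).astype(float)
        return hist / hist.sum()


@njit(cache=False)
def _glauber_kernel(n_pops, pop_size, beta, j_exc, j_inh, inhibit_within,
                    lam, n_sweeps, burn_in, seed,
                    out_counts, out_codes):  # pragma: no cover - numba
    np.random.seed(seed)
    n = n_pops * pop_size
    states = np.zeros(n, np.int8)
    counts = np.zeros(n_pops, np.int64)
    code = np.int64(0)
    for sweep in range(n_sweeps):
        for _ in range(n):
            u = np.random.randint(0, n)
            p = u // pop_size
            s_u = states[u]
            # within-population excitation from the N-1 other neurons
            h = j_exc * (counts[p] - s_u)
            # inhibition from all coupled neurons (self excluded)
            if inhibit_within:
                h -= j_inh * (counts.sum() - s_u)
            else:
                h -= j_inh * (counts.sum() - counts[p])
            h += lam[p]
            prob = 1.0 / (1.0 + np.exp(-beta * h))
            new = 1 if np.random.random() < prob else 0
            if new != s_u:
                states[u] = new
                counts[p] += new - s_u
                code ^= np.int64(1) << u
        if sweep >= burn_in:
            k = sweep - burn_in
            for p in range(n_pops):
                out_counts[k, p] = counts[p]
            out_codes[k] = code


def glauber_simulate(params: BinaryNetworkParams,
                     n_sweeps: int,
                     burn_in: int | None = None,
                     seed: int = 0) -> GlauberResult:
    """Run the Glauber chain and record one sample per sweep after burn-in.

    ``burn_in`` defaults to 10% of ``n_sweeps``.  Identical seeds give
    identical trajectories.
    """
    if burn_in is None:
        burn_in = n_sweeps // 10
    if not 0 <= burn_in < n_sweeps:
        raise InvalidParameterError("need n_sweeps > burn_in >= 0")
    n_samples = n_sweeps - burn_in
    out_counts = np.zeros((n_samples, params.n_pops), dtype=np.int64)
    out_codes = np.zeros(n_samples, dtype=np.int64)
    _glauber_kernel(
        params.n_pops, params.pop_size, params.beta,
        params.pair_j_exc, params.pair_j_inh, params.inhibit_within,
        params.external_field, n_sweeps, burn_in, int(seed) % (2 ** 31),
        out_counts, out_codes,
    )
    return GlauberResult(out_counts, out_codes, params, n_sweeps, burn_in, int(seed))
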