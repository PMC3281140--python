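"""Exact Boltzmann-ensemble treatment of small binary networks.

For systems of up to ~20 neurons the full 2**n configuration ensemble is
enumerated.  This is the oracle against which the Glauber sampler and the
mean-field solution are validated, and it yields the exact Fisher information
of the network state with respect to the population-1 input via the
exponential-family identity  F = beta**2 * Var(n_1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ..errors import EnumerationSizeError
from .model import BinaryNetworkParams, energy_from_counts

__all__ = ["ExactEnsemble", "exact_ensemble", "fisher_exact", "DEFAULT_ENUMERATION_CAP"]

DEFAULT_ENUMERATION_CAP = 20  # 2**20 ~ 1e6 states


@dataclass(frozen=True)
class ExactEnsemble:
    """Full Boltzmann-Gibbs ensemble of a small binary network.

    ``configurations`` has shape (2**n, n_pops, pop_size); ``pop_counts`` the
    per-population active counts, shape (2**n, n_pops).
    """

    configurations: np.ndarray
    pop_counts: np.ndarray
    energy: np.ndarray
    probabilities: np.ndarray
    log_partition: float
    params: BinaryNetworkParams

    def population_mean(self, pop: int) -> float:
        """Exact mean of the summed activity n_pop."""
        return float(self.probabilities @ self.pop_counts[:, pop])

    def population_variance(self, pop: int) -> float:
        """Exact variance of the summed activity n_pop."""
        n = self.pop_counts[:, pop].astype(float)
        mu = self.probabilities @ n
        return float(self.probabilities @ (n - mu) ** 2)


def exact_ensemble(params: BinaryNetworkParams,
                   cap: int = DEFAULT_ENUMERATION_CAP) -> ExactEnsemble:
    """Enumerate all configurations with their Boltzmann-Gibbs probabilities.

    Raises :class:`EnumerationSizeError` when n_pops * pop_size exceeds ``cap``.
    The log-partition is accumulated with a numerically stable log-sum-exp, and
    the returned probabilities sum to 1 to ~1e-12.
    """
    n = params.n_neurons
    if n > cap:
        raise EnumerationSizeError(
            f"system has {n} neurons, above the enumeration cap of {cap}"
        )
    codes = np.arange(2 ** n, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n)) & 1  # (2**n, n), neuron-major
    configs = bits.astype(np.uint8).reshape(-1, params.n_pops, params.pop_size)
    counts = configs.sum(axis=2).astype(np.int64)
    e = energy_from_counts(counts, params)
    logw = -params.beta * e
    log_z = float(logsumexp(logw))
    probs = np.exp(logw - log_z)
    return ExactEnsemble(
        configurations=configs,
        pop_counts=counts,
        energy=e,
        probabilities=probs,
        log_partition=log_z,
        params=params,
    )


def fisher_exact(params: BinaryNetworkParams,
                 cap: int = DEFAULT_ENUMERATION_CAP):
    """Exact Fisher information of the network state w.r.t. the population-1 input.

    The energy is linear in lambda_1 with coefficient -n_1, so the Boltzmann
    family is exponential in lambda_1 and the Fisher information equals
    beta**2 * Var(n_1) under the exact ensemble.  Returns a
    :class:`~balanced_coding.estimator.FisherEstimate` tagged "exact-binary".
    """
    from ..estimator import FisherEstimate

    ens = exact_ensemble(params, cap=cap)
    value = params.beta ** 2 * ens.population_variance(0)
    return FisherEstimate(value=float(value), method="exact-binary")
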