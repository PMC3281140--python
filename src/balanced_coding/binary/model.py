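"""Stochastic binary (Ising-like) network: parameters, single-neuron activation,
local fields and the configuration energy.

The network is a set of ``n_pops`` stimulus-selective populations of ``pop_size``
stochastic binary neurons.  Each neuron is active (state 1) with a logistic
probability of its total input, which makes the asynchronous (Glauber) dynamics
relax, for symmetric couplings, to a Boltzmann-Gibbs distribution over
configurations.  Within a population neurons excite each other with the cohesion
level ``w_plus``; the inhibition level ``w_inh`` couples neurons negatively —
by default globally (within and across populations), mirroring the single
shared inhibitory pool of the biophysical model.  Population 1 (index 0) may
receive an extra top-down ``bias`` on top of its external input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np

from ..errors import InvalidParameterError

__all__ = [
    "BinaryNetworkParams",
    "activation_probability",
    "local_field",
    "energy",
]


@dataclass(frozen=True)
class BinaryNetworkParams:
    """Parameters of the stochastic binary network.

    Parameters
    ----------
    n_pops
        Number of mutually inhibiting selective populations (>= 2).
    pop_size
        Neurons per population (>= 1).
    beta
        Inverse temperature (> 0); larger beta means less noisy neurons.
    w_plus
        Within-population excitatory weight, the "cohesion level" (>= 0).
    w_inh
        Inhibitory coupling weight, the "inhibition level" (>= 0).
    inputs
        External stimulation lambda_i, one value per population.
    bias
        Extra top-down input added to population 1 (index 0) only.
    inhibit_within
        If True (default) inhibition acts on every population including the
        source's own, as a global inhibitory pool would; if False it acts only
        across populations.
    pair_scaling
        If True (default) pair couplings are scaled by the relevant neuron
        count (w_plus/(pop_size-1) within, w_inh/pop_size per source
        population) so that the population-level mean-field equations carry
        the size-free weights w_plus and w_inh.
    """

    n_pops: int
    pop_size: int
    beta: float
    w_plus: float
    w_inh: float
    inputs: tuple[float, ...]
    bias: float = 0.0
    inhibit_within: bool = True
    pair_scaling: bool = True

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise InvalidParameterError("n_pops must be >= 2")
        if self.pop_size < 1:
            raise InvalidParameterError("pop_size must be >= 1")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise InvalidParameterError("beta must be finite and > 0")
        if self.w_plus < 0 or self.w_inh < 0:
            raise InvalidParameterError("w_plus and w_inh must be >= 0")
        if self.bias < 0:
            raise InvalidParameterError("bias must be >= 0")
        object.__setattr__(self, "inputs", tuple(float(x) for x in self.inputs))
        if len(self.inputs) != self.n_pops:
            raise InvalidParameterError(
                f"inputs must have exactly n_pops={self.n_pops} entries"
            )
        if not all(np.isfinite(self.inputs)):
            raise InvalidParameterError("inputs must be finite")

    # -- derived quantities -------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return self.n_pops * self.pop_size

    @property
    def effective_w_plus(self) -> float:
        """Population-level excitatory weight entering the mean-field equations."""
        if self.pair_scaling:
            return self.w_plus
        return self.w_plus * max(self.pop_size - 1, 0)

    @property
    def effective_w_inh(self) -> float:
        """Population-level inhibitory weight entering the mean-field equations."""
        if self.pair_scaling:
            return self.w_inh
        return self.w_inh * self.pop_size

    @property
    def pair_j_exc(self) -> float:
        """Excitatory coupling between two distinct neurons of one population."""
        if self.pop_size == 1:
            return 0.0
        return self.effective_w_plus / (self.pop_size - 1)

    @property
    def pair_j_inh(self) -> float:
        """Magnitude of the inhibitory coupling between two coupled neurons."""
        return self.effective_w_inh / self.pop_size

    @property
    def external_field(self) -> np.ndarray:
        """Per-population external input including the bias on population 1."""
        lam = np.asarray(self.inputs, dtype=float).copy()
        lam[0] += self.bias
        return lam

    def with_bias(self, bias: float) -> "BinaryNetworkParams":
        return replace(self, bias=bias)

    def with_w_inh(self, w_inh: float) -> "BinaryNetworkParams":
        return replace(self, w_inh=w_inh)


def activation_probability(field: float, beta: float):
    """Probability that a stochastic binary neuron is active given its input.

    The logistic response  p = 1 / (1 + exp(-beta * field)); strictly
    increasing in ``field``, with p(0) = 1/2 and p(h) + p(-h) = 1.
    """
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise InvalidParameterError("field must be finite")
    if not np.isfinite(beta) or beta <= 0:
        raise InvalidParameterError("beta must be finite and > 0")
    from scipy.special import expit

    out = expit(beta * field)
    return float(out) if out.ndim == 0 else out


def _activities(params: BinaryNetworkParams,
                activities: Union[Sequence[float], np.ndarray]) -> np.ndarray:
    """Normalize an activity argument to per-population means in [0, 1]."""
    arr = np.asarray(activities, dtype=float)
    if arr.ndim == 2:
        if arr.shape != (params.n_pops, params.pop_size):
            raise InvalidParameterError(
                f"configuration shape {arr.shape} != "
                f"({params.n_pops}, {params.pop_size})"
            )
        if not np.isin(arr, (0.0, 1.0)).all():
            raise InvalidParameterError("spin configuration entries must be 0 or 1")
        return arr.mean(axis=1)
    if arr.shape != (params.n_pops,):
        raise InvalidParameterError(
            f"activities must have shape ({params.n_pops},), got {arr.shape}"
        )
    return arr


def local_field(params: BinaryNetworkParams,
                activities: Union[Sequence[float], np.ndarray],
                pop: int) -> float:
    """Total input to a neuron of population ``pop`` (identical within a pool).

    ``activities`` may be per-population mean activities or a full
    (n_pops, pop_size) spin configuration, in which case population means are
    used.  The field is

        h_p = w+ m_p - wI * sum(inhibition sources) + lambda_p [+ bias if p=0]

    where the inhibition sum runs over all populations (default) or over the
    other populations only when ``inhibit_within`` is False.
    """
    if not 0 <= pop < params.n_pops:
        raise IndexError(f"population index {pop} out of range [0, {params.n_pops})")
    m = _activities(params, activities)
    inh_sum = m.sum() if params.inhibit_within else m.sum() - m[pop]
    h = (params.effective_w_plus * m[pop]
         - params.effective_w_inh * inh_sum
         + params.external_field[pop])
    return float(h)


def energy(config: np.ndarray, params: BinaryNetworkParams) -> float:
    """Energy of a spin configuration under the symmetric pair couplings.

    The Boltzmann weight exp(-beta * E) of this energy is the stationary
    distribution of the Glauber dynamics.  E depends on the configuration only
    through the per-population active counts n_i:

        E = -(j_exc - j_in_within) * sum_i n_i (n_i - 1) / 2
            + j_inh * sum_{i<j} n_i n_j
            - sum_i lambda_i n_i  (lambda_1 includes the bias)

    with j_exc = w+/(N-1) and j_inh = wI/N (pair scaling on).  Its partial
    derivative with respect to the population-1 input is minus the summed
    population-1 activity, the identity underlying the exact Fisher
    information.
    """
    config = np.asarray(config)
    if config.shape != (params.n_pops, params.pop_size):
        raise InvalidParameterError(
            f"configuration shape {config.shape} != "
            f"({params.n_pops}, {params.pop_size})"
        )
    n = config.sum(axis=1).astype(float)
    return float(energy_from_counts(n, params))


def energy_from_counts(counts: np.ndarray, params: BinaryNetworkParams):
    """Vectorized energy for per-population active counts (last axis = pops)."""
    n = np.asarray(counts, dtype=float)
    j_exc = params.pair_j_exc
    j_inh = params.pair_j_inh
    within_pairs = (n * (n - 1.0) / 2.0).sum(axis=-1)
    total = n.sum(axis=-1)
    cross_pairs = (total ** 2 - (n ** 2).sum(axis=-1)) / 2.0
    j_within = j_exc - (j_inh if params.inhibit_within else 0.0)
    e = -j_within * within_pairs + j_inh * cross_pairs
    e -= n @ params.external_field
    return e
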