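"""Network assembly: pool structure and the pool-level weight matrix.

The network is fully connected, so a synapse's weight depends only on the
(presynaptic pool, postsynaptic pool) pair.  Pools are indexed

    0 .. P-1   selective excitatory pools (pool 0 receives the bias),
    P          non-selective excitatory neurons,
    P + 1      the inhibitory population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..errors import InvalidParameterError
from .params import (
    EXC_NEURON,
    INH_NEURON,
    SYNAPSES,
    ArchitectureParams,
    NeuronParams,
    StimulusProtocol,
    SynapseParams,
)

__all__ = ["Network", "build_network"]


@dataclass(frozen=True)
class Network:
    """Immutable description of a (possibly downscaled) network instance."""

    arch: ArchitectureParams
    exc_params: NeuronParams
    inh_params: NeuronParams
    synapses: SynapseParams
    scale: float
    pool_sizes: np.ndarray       # neurons per pool
    pool_of: np.ndarray          # pool index per neuron
    is_excitatory: np.ndarray    # bool per neuron
    weights: np.ndarray          # (n_pools, n_pools) pre -> post

    @property
    def n_neurons(self) -> int:
        return int(self.pool_sizes.sum())

    @property
    def n_pools(self) -> int:
        return int(self.pool_sizes.size)

    @property
    def n_selective(self) -> int:
        return self.arch.n_selective_pools

    @property
    def inhibitory_pool(self) -> int:
        return self.n_pools - 1

    @property
    def nonselective_pool(self) -> int:
        return self.n_pools - 2

    @property
    def conductance_scale(self) -> float:
        """Recurrent conductances are multiplied by 1/scale so the summed
        synaptic drive is size-invariant under downscaling."""
        return 1.0 / self.scale

    def weight(self, pre: int, post: int) -> float:
        """Dimensionless weight of the synapse from neuron ``pre`` to ``post``."""
        return float(self.weights[self.pool_of[pre], self.pool_of[post]])


def build_network(arch: ArchitectureParams,
                  exc_params: NeuronParams = EXC_NEURON,
                  inh_params: NeuronParams = INH_NEURON,
                  synapses: SynapseParams = SYNAPSES,
                  scale: float = 1.0) -> Network:
    """Deterministically assemble the all-to-all network.

    Weights: w+ within a selective pool; w- between selective pools and from
    the non-selective neurons onto selective pools (the Hebbian depression);
    baseline 1 for the remaining excitatory connections; w_exc_to_inh onto the
    inhibitory population; w_I (the inhibition level) from inhibitory onto
    every excitatory pool; w_inh_to_inh within the inhibitory population.

    ``scale`` < 1 builds a reduced copy (counts * scale) whose recurrent
    conductances the simulator multiplies by 1/scale.
    """
    if not 0 < scale <= 1:
        raise InvalidParameterError("scale must be in (0, 1]")
    sarch = arch.scaled(scale) if scale != 1.0 else arch
    p = sarch.n_selective_pools
    n_nonsel = sarch.n_excitatory - p * sarch.pool_size
    if n_nonsel < 0:
        raise InvalidParameterError("pool sizes exceed excitatory count")
    pool_sizes = np.array([sarch.pool_size] * p + [n_nonsel, sarch.n_inhibitory])
    if n_nonsel == 0:
        # keep the pool indexing stable even if the non-selective pool is empty
        pool_sizes[p] = 0
    pool_of = np.repeat(np.arange(p + 2), pool_sizes)
    is_exc = pool_of < p + 1

    w = np.full((p + 2, p + 2), sarch.w_baseline, dtype=float)
    w_minus = sarch.w_minus
    # selective <-> selective
    w[:p, :p] = w_minus
    np.fill_diagonal(w[:p, :p], sarch.w_plus)
    # non-selective -> selective depressed; selective -> non-selective baseline
    w[p, :p] = w_minus
    w[:p, p] = sarch.w_baseline
    # excitatory -> inhibitory
    w[:p + 1, p + 1] = sarch.w_exc_to_inh
    # inhibitory -> excitatory (the inhibition level) and inhibitory -> inhibitory
    w[p + 1, :p + 1] = sarch.w_inh
    w[p + 1, p + 1] = sarch.w_inh_to_inh

    return Network(
        arch=sarch, exc_params=exc_params, inh_params=inh_params,
        synapses=synapses, scale=scale,
        pool_sizes=pool_sizes, pool_of=pool_of, is_excitatory=is_exc,
        weights=w,
    )
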