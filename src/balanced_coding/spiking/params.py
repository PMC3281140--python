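"""Parameters of the conductance-based integrate-and-fire attractor network.

Defaults follow the published parameter table of this model family: 800
excitatory and 200 inhibitory leaky integrate-and-fire neurons, AMPA / NMDA /
GABA-A conductance-based synapses, NMDA with slow second-order kinetics and a
voltage-dependent magnesium block, and a fully connected architecture in which
the excitatory neurons are organized into stimulus-selective pools (cohesion
weight w+ inside a pool, depressed weight w- between pools) competing through
a single global inhibitory population whose efficacy onto excitatory cells is
the inhibition level w_I.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from ..errors import InvalidParameterError

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "ArchitectureParams",
    "StimulusProtocol",
    "EXC_NEURON",
    "INH_NEURON",
    "SYNAPSES",
    "derive_w_minus",
]


@dataclass(frozen=True)
class NeuronParams:
    """Single-compartment leaky integrate-and-fire cell."""

    membrane_capacitance: float  # nF
    leak_conductance: float      # nS
    resting_potential: float     # mV
    threshold_potential: float   # mV
    reset_potential: float       # mV
    refractory_period: float     # ms

    def __post_init__(self) -> None:
        if self.membrane_capacitance <= 0 or self.leak_conductance <= 0:
            raise InvalidParameterError("capacitance and leak conductance must be > 0")
        if self.reset_potential >= self.threshold_potential:
            raise InvalidParameterError("reset must lie below threshold")
        if self.refractory_period < 0:
            raise InvalidParameterError("refractory period must be >= 0")

    @property
    def membrane_time_constant(self) -> float:
        """tau_m = C / g_L in ms (nF / nS = s, hence the factor 1000)."""
        return self.membrane_capacitance / self.leak_conductance * 1000.0

    @property
    def threshold_current(self) -> float:
        """Constant current (nA) holding a leak-only neuron exactly at threshold:
        g_L * (V_thr - V_L)."""
        return self.leak_conductance * (
            self.threshold_potential - self.resting_potential) * 1e-3


@dataclass(frozen=True)
class SynapseParams:
    """Kinetics, reversal potentials and per-cell-class peak conductances."""

    excitatory_reversal: float = 0.0    # mV
    inhibitory_reversal: float = -70.0  # mV
    ampa_decay: float = 2.0             # ms
    nmda_rise: float = 2.0              # ms
    nmda_decay: float = 100.0           # ms
    gaba_decay: float = 10.0            # ms
    nmda_alpha: float = 0.5             # ms^-1, rise->open coupling
    mg_voltage_slope: float = 0.062     # mV^-1
    mg_concentration_factor: float = 0.2801  # [Mg2+]/3.57, dimensionless
    # peak conductances (nS), columns of the parameter table
    exc_g_ampa_ext: float = 2.08
    exc_g_ampa_rec: float = 0.104
    exc_g_nmda: float = 0.327
    exc_g_gaba: float = 1.25
    inh_g_ampa_ext: float = 1.62
    inh_g_ampa_rec: float = 0.081
    inh_g_nmda: float = 0.258
    inh_g_gaba: float = 0.973

    def __post_init__(self) -> None:
        for name in ("ampa_decay", "nmda_rise", "nmda_decay", "gaba_decay",
                     "exc_g_ampa_ext", "exc_g_ampa_rec", "exc_g_nmda",
                     "exc_g_gaba", "inh_g_ampa_ext", "inh_g_ampa_rec",
                     "inh_g_nmda", "inh_g_gaba"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.nmda_decay <= self.nmda_rise:
            raise InvalidParameterError("nmda_decay must exceed nmda_rise")


#: Table defaults: excitatory (pyramidal) cells
EXC_NEURON = NeuronParams(
    membrane_capacitance=0.5, leak_conductance=25.0,
    resting_potential=-70.0, threshold_potential=-50.0,
    reset_potential=-55.0, refractory_period=1.0,
)

#: Table defaults: inhibitory interneurons
INH_NEURON = NeuronParams(
    membrane_capacitance=0.2, leak_conductance=20.0,
    resting_potential=-70.0, threshold_potential=-50.0,
    reset_potential=-55.0, refractory_period=1.0,
)

SYNAPSES = SynapseParams()


def derive_w_minus(w_plus: float, selective_fraction: float) -> float:
    """Depressed inter-pool weight keeping the average excitatory efficacy at 1.

    w- = 1 - f (w+ - 1) / (1 - f), so that f w+ + (1 - f) w- = 1 for the
    selective fraction f.  Requires w+ >= 1 and a result in [0, 1].
    """
    if not 0 < selective_fraction < 1:
        raise InvalidParameterError("selective_fraction must be in (0, 1)")
    if w_plus < 1:
        raise InvalidParameterError("w_plus must be >= 1 (potentiated weight)")
    w_minus = 1.0 - selective_fraction * (w_plus - 1.0) / (1.0 - selective_fraction)
    if w_minus < 0:
        raise InvalidParameterError(
            f"w_plus={w_plus} too large: derived w_minus would be negative"
        )
    return w_minus


@dataclass(frozen=True)
class ArchitectureParams:
    """Counts, pool structure and dimensionless connection weights.

    The fully connected network has three population types: the selective
    excitatory pools, the non-selective excitatory remainder, and one global
    inhibitory population.  ``w_minus`` is derived from the
    constant-average-efficacy relation when not given explicitly.  The
    external drive is n_external Poisson sources at external_rate each,
    statistically equivalent to one train at their summed rate.
    """

    n_excitatory: int = 800
    n_inhibitory: int = 200
    n_selective_pools: int = 2
    pool_size: int = 80
    w_plus: float = 1.9
    w_inh: float = 1.0
    w_baseline: float = 1.0
    w_exc_to_inh: float = 1.0
    w_inh_to_inh: float = 1.0
    n_external: int = 800
    external_rate: float = 3.0  # Hz per source
    w_minus_override: float | None = None

    def __post_init__(self) -> None:
        if self.n_selective_pools < 1 or self.pool_size < 1:
            raise InvalidParameterError("need at least one selective pool")
        if self.n_selective_pools * self.pool_size > self.n_excitatory:
            raise InvalidParameterError(
                "selective pools cannot exceed the excitatory population"
            )
        for name in ("w_plus", "w_inh", "w_baseline", "w_exc_to_inh",
                     "w_inh_to_inh"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @property
    def selective_fraction(self) -> float:
        """Fraction of excitatory neurons in one selective pool."""
        return self.pool_size / self.n_excitatory

    @property
    def w_minus(self) -> float:
        if self.w_minus_override is not None:
            return self.w_minus_override
        if self.w_plus <= 1.0:
            return 1.0
        return derive_w_minus(self.w_plus, self.selective_fraction)

    @property
    def total_external_rate(self) -> float:
        """Summed background Poisson rate per neuron, in Hz."""
        return self.n_external * self.external_rate

    def with_w_inh(self, w_inh: float) -> "ArchitectureParams":
        return replace(self, w_inh=w_inh)

    def scaled(self, scale: float) -> "ArchitectureParams":
        """Downscale neuron counts by ``scale`` (conductances are rescaled by
        1/scale at network build so the mean synaptic drive is preserved)."""
        if not 0 < scale <= 1:
            raise InvalidParameterError("scale must be in (0, 1]")
        return replace(
            self,
            n_excitatory=max(int(round(self.n_excitatory * scale)), 2),
            n_inhibitory=max(int(round(self.n_inhibitory * scale)), 1),
            pool_size=max(int(round(self.pool_size * scale)), 1),
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """Trial structure and external drive.

    A trial is ``stabilization_ms`` of background-only activity followed by
    ``stimulus_ms`` during which every selective pool receives an extra
    ``stimulus_rate`` and pool 1 additionally the ``bias_rate`` (which may be
    negative for the centered finite difference around zero bias; the total
    external rate is rectified at zero).  The background rate fluctuates as a
    mean-reverting (Ornstein-Uhlenbeck) process with standard deviation
    ``noise_sigma`` and correlation time ``noise_tau``, independently per
    population, with negative excursions rectified to zero.
    """

    stabilization_ms: float = 500.0
    stimulus_ms: float = 1000.0
    stimulus_rate: float = 120.0  # Hz, to all selective pools
    bias_rate: float = 0.0        # Hz, to pool 1 only
    noise_sigma: float = 50.0     # Hz
    noise_tau: float = 10.0       # ms

    def __post_init__(self) -> None:
        if self.stabilization_ms <= 0 or self.stimulus_ms <= 0:
            raise InvalidParameterError("durations must be > 0")
        if self.stimulus_rate < 0:
            raise InvalidParameterError("stimulus_rate must be >= 0")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if self.noise_sigma > 0 and self.noise_tau <= 0:
            raise InvalidParameterError("noise_tau must be > 0 when noise_sigma > 0")

    @property
    def duration_ms(self) -> float:
        return self.stabilization_ms + self.stimulus_ms

    def with_bias(self, bias_rate: float) -> "StimulusProtocol":
        return replace(self, bias_rate=bias_rate)
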