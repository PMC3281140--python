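"""Fixed-step simulation of the conductance-based attractor network.

Integration is exponential-Euler throughout: membrane potentials advance with
the instantaneous total conductance held fixed over the step, first-order
gating variables (AMPA, GABA, NMDA rise) decay exactly, and the saturating
NMDA open fraction is advanced with its rise variable frozen within the step.
Spikes are detected after the full step, reset is immediate, and the neuron is
clamped at reset for its refractory period.  All randomness (external Poisson
arrivals, background-rate fluctuations) derives from one integer seed, so a
trial is bit-for-bit reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ..errors import InvalidParameterError, SimulationError
from .background import background_rate_process
from .network import Network
from .params import NeuronParams, StimulusProtocol
from .raster import CurrentRecord, SpikeRaster

__all__ = [
    "simulate_trial",
    "run_trials",
    "lif_rate_analytic",
    "simulate_lif_constant_current",
]

_SPIKE_CAP_HZ = 600.0  # per-neuron recording headroom


@njit(inline="always", cache=False)
def _exp_neg(z):  # pragma: no cover - numba
    """exp(-z) for z >= 0; cubic Taylor below 0.05 (rel. error < 3e-7)."""
    if z < 0.05:
        return 1.0 - z * (1.0 - 0.5 * z * (1.0 - z / 3.0))
    return math.exp(-z)


#: magnesium-block lookup table domain (mV) and resolution
_MG_VMIN = -150.0
_MG_VMAX = 50.0
_MG_STEP = 0.05


def _mg_table(mg_f: float, mg_slope: float) -> np.ndarray:
    """Tabulated 1/(1 + mg_f exp(-mg_slope V)) for linear interpolation."""
    v = np.arange(_MG_VMIN, _MG_VMAX + _MG_STEP, _MG_STEP)
    return 1.0 / (1.0 + mg_f * np.exp(-mg_slope * v))


@njit(cache=False)
def _kernel(n_steps, dt, n, pool_of, is_exc,
            cm, gl, vl, vth, vr, tref, i_inject,
            g_ampa_ext, g_ampa_rec, g_nmda, g_gaba,
            w, ve, vi, e_ampa, e_gaba, e_rise,
            inv_tau_nmda, alpha, mg_tab,
            ext_rate, seed,
            spike_t, spike_i, currents, record_currents):  # pragma: no cover
    np.random.seed(seed)
    n_pools = w.shape[0]
    v = vl.copy()
    inv_cm_dt = dt / (cm * 1000.0)  # dt/tau_eff = g_tot * inv_cm_dt (nF/nS = s)
    inv_mg_step = 1.0 / _MG_STEP
    ref_left = np.zeros(n)
    s_ext = np.zeros(n)
    s_ampa = np.zeros(n)
    x_nmda = np.zeros(n)
    s_nmda = np.zeros(n)
    s_gaba = np.zeros(n)
    pool_n = np.zeros(n_pools)
    for i in range(n):
        pool_n[pool_of[i]] += 1.0
    inv_pool_n = np.zeros(n_pools)
    for p in range(n_pools):
        inv_pool_n[p] = 1.0 / pool_n[p] if pool_n[p] > 0 else 0.0
    sum_ampa = np.zeros(n_pools)
    sum_nmda = np.zeros(n_pools)
    sum_gaba = np.zeros(n_pools)
    in_ampa = np.zeros(n_pools)
    in_nmda = np.zeros(n_pools)
    in_gaba = np.zeros(n_pools)
    lam_pool = np.zeros(n_pools)
    p0_pool = np.zeros(n_pools)
    n_spikes = 0
    cap = spike_t.shape[0]
    e_nmda_decay = _exp_neg(dt * inv_tau_nmda)
    for t in range(n_steps):
        for p in range(n_pools):
            lam = ext_rate[t, p] * 1e-3 * dt
            lam_pool[p] = lam
            p0_pool[p] = math.exp(-lam)
            sum_ampa[p] = 0.0
            sum_nmda[p] = 0.0
            sum_gaba[p] = 0.0
        # presynaptic gating decay + external Poisson arrivals + pool sums
        for i in range(n):
            p = pool_of[i]
            lam = lam_pool[p]
            arrivals = 0
            if lam > 0.0:
                u = np.random.random()
                pr = p0_pool[p]
                while u > pr and arrivals < 64:
                    u -= pr
                    arrivals += 1
                    pr *= lam / arrivals
            s_ext[i] = s_ext[i] * e_ampa + arrivals
            if is_exc[i]:
                s_ampa[i] *= e_ampa
                x = x_nmda[i] * e_rise
                x_nmda[i] = x
                k = inv_tau_nmda + alpha * x
                s_inf = alpha * x / k
                s = s_inf + (s_nmda[i] - s_inf) * _exp_neg(dt * k)
                s_nmda[i] = s
                sum_ampa[p] += s_ampa[i]
                sum_nmda[p] += s
            else:
                s_gaba[i] *= e_gaba
                sum_gaba[p] += s_gaba[i]
        # weighted input per postsynaptic pool
        for post in range(n_pools):
            a = 0.0
            b = 0.0
            c = 0.0
            for pre in range(n_pools):
                wij = w[pre, post]
                a += wij * sum_ampa[pre]
                b += wij * sum_nmda[pre]
                c += wij * sum_gaba[pre]
            in_ampa[post] = a
            in_nmda[post] = b
            in_gaba[post] = c
        # membrane update
        for i in range(n):
            p = pool_of[i]
            vm = v[i]
            # voltage-dependent NMDA magnesium block via table interpolation
            fpos = (vm - _MG_VMIN) * inv_mg_step
            k0 = int(fpos)
            frac = fpos - k0
            mg = mg_tab[k0] * (1.0 - frac) + mg_tab[k0 + 1] * frac
            # self-connections (autapses) are excluded: subtract own gating
            w_self = w[p, p]
            if is_exc[i]:
                rec_ampa = in_ampa[p] - w_self * s_ampa[i]
                rec_nmda = in_nmda[p] - w_self * s_nmda[i]
                rec_gaba = in_gaba[p]
            else:
                rec_ampa = in_ampa[p]
                rec_nmda = in_nmda[p]
                rec_gaba = in_gaba[p] - w_self * s_gaba[i]
            ga = g_ampa_ext[i] * s_ext[i] + g_ampa_rec[i] * rec_ampa
            gn = g_nmda[i] * rec_nmda * mg
            gg = g_gaba[i] * rec_gaba
            if record_currents:
                currents[t, p, 0] += (ga + gn) * (ve - vm)
                currents[t, p, 1] += gg * (vi - vm)
            if ref_left[i] > 0.0:
                ref_left[i] -= dt
                v[i] = vr[i]
                continue
            g_tot = gl[i] + ga + gn + gg
            inv_g = 1.0 / g_tot
            v_inf = (gl[i] * vl[i] + (ga + gn) * ve + gg * vi
                     + i_inject[i] * 1e3) * inv_g
            v_new = v_inf + (vm - v_inf) * _exp_neg(g_tot * inv_cm_dt[i])
            if v_new >= vth[i]:
                if n_spikes < cap:
                    spike_t[n_spikes] = (t + 1) * dt
                    spike_i[n_spikes] = i
                n_spikes += 1
                v[i] = vr[i]
                ref_left[i] = tref[i]
                if is_exc[i]:
                    s_ampa[i] += 1.0
                    x_nmda[i] += 1.0
                else:
                    s_gaba[i] += 1.0
            else:
                if v_new < -150.0 or v_new > 50.0:
                    return -1
                v[i] = v_new
        if record_currents:
            for p in range(n_pools):
                currents[t, p, 0] *= inv_pool_n[p] * 1e-3  # pA -> nA
                currents[t, p, 1] *= inv_pool_n[p] * 1e-3
    return n_spikes


def _external_rate_series(network: Network, protocol: StimulusProtocol,
                          dt: float, rng: np.random.Generator) -> np.ndarray:
    """Total external rate per pool and step: fluctuating background plus
    stimulus (selective pools) and bias (pool 0) during the stimulus window,
    rectified at zero."""
    rate = background_rate_process(
        protocol, dt, protocol.duration_ms, network.n_pools,
        network.arch.total_external_rate, rng,
    )
    t0 = int(round(protocol.stabilization_ms / dt))
    rate[t0:, :network.n_selective] += protocol.stimulus_rate
    rate[t0:, 0] += protocol.bias_rate
    return np.clip(rate, 0.0, None)


def _per_neuron_arrays(network: Network):
    is_exc = network.is_excitatory
    syn = network.synapses
    csc = network.conductance_scale

    def pick(exc_val, inh_val):
        return np.where(is_exc, exc_val, inh_val).astype(float)

    ep, ip = network.exc_params, network.inh_params
    return dict(
        cm=pick(ep.membrane_capacitance, ip.membrane_capacitance),
        gl=pick(ep.leak_conductance, ip.leak_conductance),
        vl=pick(ep.resting_potential, ip.resting_potential),
        vth=pick(ep.threshold_potential, ip.threshold_potential),
        vr=pick(ep.reset_potential, ip.reset_potential),
        tref=pick(ep.refractory_period, ip.refractory_period),
        g_ampa_ext=pick(syn.exc_g_ampa_ext, syn.inh_g_ampa_ext),
        g_ampa_rec=pick(syn.exc_g_ampa_rec, syn.inh_g_ampa_rec) * csc,
        g_nmda=pick(syn.exc_g_nmda, syn.inh_g_nmda) * csc,
        g_gaba=pick(syn.exc_g_gaba, syn.inh_g_gaba) * csc,
    )


def simulate_trial(network: Network,
                   protocol: StimulusProtocol,
                   dt: float = 0.05,
                   seed: int = 0,
                   trial_id: int = 0,
                   i_inject: np.ndarray | None = None,
                   record_currents: bool = True
                   ) -> tuple[SpikeRaster, CurrentRecord]:
    """Integrate one trial and return its spike raster and current record.

    ``dt`` must be <= 0.1 ms to resolve the NMDA rise and the refractory
    period.  ``i_inject`` optionally adds a constant current (nA, per neuron),
    used for single-neuron validation.  The raster records (neuron, time)
    events; the current record holds, per pool and step, the pool-mean
    excitatory (>= 0) and inhibitory (<= 0) synaptic drives in nA.
    """
    if dt <= 0 or dt > 0.1:
        raise InvalidParameterError("dt must be in (0, 0.1] ms")
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), 2 ** 16 + trial_id])
    ou_seed, poisson_seed = ss.spawn(2)
    rng = np.random.default_rng(ou_seed)
    ext_rate = _external_rate_series(network, protocol, dt, rng)
    n_steps = ext_rate.shape[0]
    n = network.n_neurons
    cap = int(n * protocol.duration_ms * 1e-3 * _SPIKE_CAP_HZ)
    spike_t = np.zeros(cap)
    spike_i = np.zeros(cap, dtype=np.int64)
    currents = np.zeros((n_steps, network.n_pools, 2)) if record_currents \
        else np.zeros((1, network.n_pools, 2))
    if i_inject is None:
        i_inject = np.zeros(n)
    arrs = _per_neuron_arrays(network)
    syn = network.synapses
    n_spikes = _kernel(
        n_steps, dt, n,
        network.pool_of.astype(np.int64),
        network.is_excitatory.astype(np.bool_),
        arrs["cm"], arrs["gl"], arrs["vl"], arrs["vth"], arrs["vr"],
        arrs["tref"], np.asarray(i_inject, dtype=float),
        arrs["g_ampa_ext"], arrs["g_ampa_rec"], arrs["g_nmda"], arrs["g_gaba"],
        network.weights,
        syn.excitatory_reversal, syn.inhibitory_reversal,
        math.exp(-dt / syn.ampa_decay), math.exp(-dt / syn.gaba_decay),
        math.exp(-dt / syn.nmda_rise),
        1.0 / syn.nmda_decay, syn.nmda_alpha,
        _mg_table(syn.mg_concentration_factor, syn.mg_voltage_slope),
        ext_rate, int(poisson_seed.generate_state(1)[0] % (2 ** 31)),
        spike_t, spike_i, currents, record_currents,
    )
    if n_spikes < 0:
        raise SimulationError(
            "membrane potential left physical bounds; check parameters/dt"
        )
    if n_spikes > cap:
        raise SimulationError(
            f"spike buffer overflow ({n_spikes} > {cap}); network is epileptic"
        )
    raster = SpikeRaster(
        trial=trial_id,
        times=spike_t[:n_spikes].copy(),
        neurons=spike_i[:n_spikes].copy(),
        pool_of=network.pool_of.copy(),
        duration_ms=protocol.duration_ms,
    )
    record = CurrentRecord(
        time_ms=(np.arange(currents.shape[0]) + 1) * dt,
        excitatory=currents[:, :, 0].copy(),
        inhibitory=currents[:, :, 1].copy(),
        threshold_current=network.exc_params.threshold_current,
    )
    return raster, record


def run_trials(network: Network,
               protocol: StimulusProtocol,
               n_trials: int,
               dt: float = 0.05,
               seed: int = 0,
               pool: int = 0,
               window_ms: tuple[float, float] | None = None,
               record_currents: bool = True):
    """Simulate ``n_trials`` independent trials; return pool spike counts and
    the trial-averaged stimulus-window pool currents.

    Returns ``(counts, mean_exc_nA, mean_inh_nA)`` where ``counts`` is the
    per-trial summed spike count of ``pool`` inside ``window_ms`` (default:
    the first 500 ms of the stimulus period).
    """
    from .raster import pool_spike_counts

    if window_ms is None:
        window_ms = (protocol.stabilization_ms,
                     min(protocol.stabilization_ms + 500.0,
                         protocol.duration_ms))
    counts = np.zeros(n_trials, dtype=np.int64)
    exc_acc = 0.0
    inh_acc = 0.0
    for k in range(n_trials):
        raster, record = simulate_trial(network, protocol, dt=dt,
                                        seed=seed, trial_id=k,
                                        record_currents=record_currents)
        counts[k] = pool_spike_counts(raster, pool, window_ms).sum()
        if record_currents:
            sel = (record.time_ms >= window_ms[0]) \
                & (record.time_ms < window_ms[1])
            exc_acc += record.excitatory[sel, pool].mean()
            inh_acc += record.inhibitory[sel, pool].mean()
    if not record_currents:
        return counts, float("nan"), float("nan")
    return counts, exc_acc / n_trials, inh_acc / n_trials


# ---------------------------------------------------------------------------
# single-neuron validation helpers

def lif_rate_analytic(params: NeuronParams, current_nA: float) -> float:
    """Stationary firing rate (Hz) of a leaky IF neuron under constant current.

    rate = 1 / (t_ref + tau_m ln((V_inf - V_reset)/(V_inf - V_thr))) for
    suprathreshold drive, 0 otherwise; V_inf = V_L + I / g_L.
    """
    v_inf = params.resting_potential + current_nA * 1e3 / params.leak_conductance
    if v_inf <= params.threshold_potential:
        return 0.0
    tau = params.membrane_time_constant
    isi_ms = params.refractory_period + tau * math.log(
        (v_inf - params.reset_potential) / (v_inf - params.threshold_potential)
    )
    return 1000.0 / isi_ms


def simulate_lif_constant_current(params: NeuronParams,
                                  current_nA: float,
                                  duration_ms: float,
                                  dt: float = 0.02) -> np.ndarray:
    """Spike times (ms) of one deterministic leak-only neuron under constant
    current, routed through the network kernel (single neuron, all synaptic
    input silenced)."""
    from .network import build_network
    from .params import ArchitectureParams

    arch = ArchitectureParams(
        n_excitatory=2, n_inhibitory=1, n_selective_pools=1, pool_size=1,
        w_plus=1.0, external_rate=0.0,
    )
    net = build_network(arch, exc_params=params)
    protocol = StimulusProtocol(
        stabilization_ms=dt, stimulus_ms=duration_ms,
        stimulus_rate=0.0, noise_sigma=0.0,
    )
    i_inject = np.zeros(net.n_neurons)
    i_inject[0] = current_nA
    raster, _ = simulate_trial(net, protocol, dt=dt, seed=0,
                               i_inject=i_inject, record_currents=False)
    return raster.times[raster.neurons == 0]
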