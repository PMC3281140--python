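"""Spiking network: weights, background process, integrator, counting."""

import numpy as np
import pytest

from balanced_coding.errors import InvalidParameterError
from balanced_coding.spiking import (
    EXC_NEURON,
    INH_NEURON,
    ArchitectureParams,
    SpikeRaster,
    StimulusProtocol,
    background_rate_process,
    build_network,
    counts_from_rasters,
    derive_w_minus,
    lif_rate_analytic,
    mean_current_vs_threshold,
    pool_spike_counts,
    simulate_lif_constant_current,
    simulate_trial,
)


class TestDeriveWMinus:
    def test_no_potentiation_no_depression(self):
        assert derive_w_minus(1.0, 0.1) == 1.0

    @pytest.mark.parametrize("w_plus,f", [(1.9, 0.1), (1.5, 0.2), (2.5, 0.05)])
    def test_constant_average_efficacy_identity(self, w_plus, f):
        w_minus = derive_w_minus(w_plus, f)
        assert f * w_plus + (1 - f) * w_minus == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= w_minus <= 1.0

    def test_table_default_cohesion(self):
        arch = ArchitectureParams()
        assert arch.w_plus == 1.9
        assert arch.w_minus == pytest.approx(
            1 - 0.1 * 0.9 / 0.9)  # f = 80/800
        assert arch.selective_fraction == pytest.approx(0.1)

    def test_excessive_potentiation_rejected(self):
        with pytest.raises(InvalidParameterError):
            derive_w_minus(12.0, 0.1)


class TestBuildNetwork:
    def test_pool_weight_lookups(self):
        net = build_network(ArchitectureParams(w_inh=1.3))
        arch = net.arch
        first_pool1 = 0
        first_pool2 = arch.pool_size
        nonsel = arch.n_selective_pools * arch.pool_size
        inh = arch.n_excitatory
        # within-pool cohesion / between-pool depression
        assert net.weight(first_pool1, first_pool1 + 1) == arch.w_plus
        assert net.weight(first_pool1, first_pool2) == pytest.approx(arch.w_minus)
        assert net.weight(nonsel, first_pool1) == pytest.approx(arch.w_minus)
        # baseline and inhibition level
        assert net.weight(nonsel, nonsel + 1) == 1.0
        assert net.weight(first_pool1, nonsel) == 1.0
        assert net.weight(inh, first_pool1) == 1.3
        assert net.weight(inh, inh + 1) == arch.w_inh_to_inh
        assert net.weight(first_pool1, inh) == arch.w_exc_to_inh

    def test_scaling_preserves_pool_structure(self):
        net = build_network(ArchitectureParams(), scale=0.25)
        assert net.pool_sizes.tolist() == [20, 20, 160, 50]
        assert net.conductance_scale == 4.0

    def test_deterministic(self):
        a = build_network(ArchitectureParams())
        b = build_network(ArchitectureParams())
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.pool_of, b.pool_of)


class TestBackgroundRate:
    def test_noiseless_limit_constant(self):
        proto = StimulusProtocol(noise_sigma=0.0)
        r = background_rate_process(proto, 0.1, 100.0, 3, 2400.0, seed=0)
        assert r.shape == (1000, 3)
        assert np.all(r == 2400.0)

    def test_stationary_mean_and_variance(self):
        proto = StimulusProtocol(noise_sigma=50.0, noise_tau=10.0)
        r = background_rate_process(proto, 0.1, 200_000.0, 2, 2400.0, seed=1)
        # 2400 >> sigma: rectification never triggers here
        assert r.min() > 0
        assert r.mean() == pytest.approx(2400.0, abs=3.0)
        assert r.std() == pytest.approx(50.0, rel=0.05)

    def test_pools_independent(self):
        proto = StimulusProtocol(noise_sigma=50.0, noise_tau=10.0)
        r = background_rate_process(proto, 0.1, 50_000.0, 2, 2400.0, seed=2)
        rho = np.corrcoef(r[:, 0], r[:, 1])[0, 1]
        assert abs(rho) < 0.05


class TestSimulateTrial:
    def test_no_input_no_spikes(self, tiny_network):
        proto = StimulusProtocol(stabilization_ms=100.0, stimulus_ms=100.0,
                                 stimulus_rate=0.0, noise_sigma=0.0)
        silent = build_network(
            ArchitectureParams(external_rate=0.0), scale=0.1)
        raster, record = simulate_trial(silent, proto, dt=0.1, seed=0)
        assert raster.n_spikes == 0
        assert np.allclose(record.total, 0.0)
        # silent network sits exactly threshold_current below threshold
        assert mean_current_vs_threshold(record) == pytest.approx(
            -EXC_NEURON.threshold_current)

    def test_bitwise_reproducibility(self, tiny_network, short_protocol):
        r1, c1 = simulate_trial(tiny_network, short_protocol, dt=0.1, seed=9)
        r2, c2 = simulate_trial(tiny_network, short_protocol, dt=0.1, seed=9)
        r3, _ = simulate_trial(tiny_network, short_protocol, dt=0.1, seed=10)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.neurons, r2.neurons)
        assert np.array_equal(c1.excitatory, c2.excitatory)
        assert not np.array_equal(r1.times, r3.times)

    def test_refractory_never_violated(self, tiny_network, short_protocol):
        raster, _ = simulate_trial(tiny_network, short_protocol, dt=0.1,
                                   seed=11)
        assert raster.n_spikes > 0
        for nrn, isi in raster.isi_by_neuron().items():
            tref = (EXC_NEURON if tiny_network.is_excitatory[nrn]
                    else INH_NEURON).refractory_period
            assert isi.min() >= tref

    def test_dt_validation(self, tiny_network, short_protocol):
        with pytest.raises(InvalidParameterError):
            simulate_trial(tiny_network, short_protocol, dt=0.2)

    def test_current_signs(self, tiny_network, short_protocol):
        _, record = simulate_trial(tiny_network, short_protocol, dt=0.1,
                                   seed=12)
        assert np.all(record.excitatory >= 0.0)
        assert np.all(record.inhibitory <= 0.0)


class TestLifClosedForm:
    @pytest.mark.parametrize("current", [0.55, 0.65, 0.8])
    def test_rate_matches_analytic_within_one_percent(self, current):
        spikes = simulate_lif_constant_current(EXC_NEURON, current,
                                               duration_ms=10_000.0, dt=0.02)
        assert spikes.size > 10
        rate = (spikes.size - 1) / (spikes[-1] - spikes[0]) * 1000.0
        assert rate == pytest.approx(lif_rate_analytic(EXC_NEURON, current),
                                     rel=0.01)

    def test_subthreshold_current_silent(self):
        spikes = simulate_lif_constant_current(EXC_NEURON, 0.3,
                                               duration_ms=2000.0, dt=0.02)
        assert spikes.size == 0
        assert lif_rate_analytic(EXC_NEURON, 0.3) == 0.0


class TestPoolSpikeCounts:
    def _toy_raster(self, times, neurons):
        pool_of = np.array([0, 0, 1, 1, 2])
        return SpikeRaster(trial=0, times=np.asarray(times, float),
                           neurons=np.asarray(neurons), pool_of=pool_of,
                           duration_ms=1000.0)

    def test_empty_raster_all_zeros(self):
        r = self._toy_raster([], [])
        assert pool_spike_counts(r, 0, (0, 1000)).tolist() == [0, 0]

    def test_counts_invariant_to_event_order(self):
        times = [5.0, 1.0, 3.0, 2.0, 4.0]
        neurons = [0, 1, 0, 2, 0]
        a = pool_spike_counts(self._toy_raster(times, neurons), 0, (0, 1000))
        order = np.argsort(times)
        b = pool_spike_counts(
            self._toy_raster(np.array(times)[order], np.array(neurons)[order]),
            0, (0, 1000))
        assert np.array_equal(a, b)
        assert a.tolist() == [3, 1]

    def test_unknown_pool_rejected(self):
        with pytest.raises(InvalidParameterError):
            pool_spike_counts(self._toy_raster([], []), 7, (0, 100))

    def test_poisson_surrogate_mean_count(self):
        """Homogeneous-Poisson raster at rate r: mean count = r * window."""
        rng = np.random.default_rng(13)
        rate_hz, window, n_neurons, n_trials = 20.0, 500.0, 4, 200
        pool_of = np.zeros(n_neurons, dtype=int)
        rasters = []
        for t in range(n_trials):
            events = []
            for i in range(n_neurons):
                n_ev = rng.poisson(rate_hz * window / 1000.0)
                events += [(float(x), i) for x in rng.uniform(0, window, n_ev)]
            times = np.array([e[0] for e in events])
            nrn = np.array([e[1] for e in events], dtype=int)
            rasters.append(SpikeRaster(t, times, nrn, pool_of, window))
        sample = counts_from_rasters(rasters, 0, (0.0, window))
        expected = n_neurons * rate_hz * window / 1000.0
        assert sample.mean() == pytest.approx(expected, rel=0.05)
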