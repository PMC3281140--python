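"""Single-neuron activation, local fields and the configuration energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from balanced_coding.binary import (
    BinaryNetworkParams,
    activation_probability,
    energy,
    local_field,
)
from balanced_coding.errors import InvalidParameterError


class TestActivationProbability:
    def test_zero_field_is_half(self):
        for beta in (0.1, 1.0, 7.0):
            assert activation_probability(0.0, beta) == 0.5

    @given(h=st.floats(-8, 8), beta=st.floats(0.01, 3))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetry_and_range(self, h, beta):
        # |beta*h| <= 24 keeps the logistic away from float saturation
        p = activation_probability(h, beta)
        q = activation_probability(-h, beta)
        assert 0.0 < p < 1.0
        assert p + q == pytest.approx(1.0, abs=1e-12)

    @given(beta=st.floats(0.01, 3),
           fields=st.lists(st.integers(-800, 800), min_size=2, max_size=8,
                           unique=True))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_increasing_in_field(self, beta, fields):
        fields = sorted(0.01 * f for f in fields)
        probs = [activation_probability(h, beta) for h in fields]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_zero_temperature_limit_monotone(self):
        probs = [activation_probability(0.7, b) for b in (1, 4, 16, 40)]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 1 - 1e-12

    def test_invalid_arguments(self):
        with pytest.raises(InvalidParameterError):
            activation_probability(np.inf, 1.0)
        with pytest.raises(InvalidParameterError):
            activation_probability(0.0, 0.0)
        with pytest.raises(InvalidParameterError):
            activation_probability(0.0, -2.0)


class TestLocalField:
    def test_decoupled_limit_is_external_input(self, decoupled_params):
        m = np.array([0.3, 0.9, 0.1])
        for pop in range(3):
            assert local_field(decoupled_params, m, pop) == pytest.approx(
                decoupled_params.inputs[pop])

    def test_recurrent_term_linear_in_activities(self):
        p = BinaryNetworkParams(n_pops=2, pop_size=4, beta=1.0,
                                w_plus=0.8, w_inh=0.0, inputs=(0.0, 0.0))
        m = np.array([0.2, 0.3])
        h1 = local_field(p, m, 0)
        h2 = local_field(p, 2 * m, 0)
        assert h2 == pytest.approx(2 * h1)

    def test_symmetric_inputs_bias_only_breaks_population_one(self):
        p = BinaryNetworkParams(n_pops=4, pop_size=3, beta=1.0,
                                w_plus=0.4, w_inh=0.2, inputs=(0.5,) * 4,
                                bias=0.3)
        m = np.full(4, 0.6)
        fields = [local_field(p, m, i) for i in range(4)]
        assert len(set(np.round(fields[1:], 12))) == 1
        assert fields[0] == pytest.approx(fields[1] + 0.3)

    def test_accepts_spin_configuration(self, small_params):
        config = np.array([[1, 0], [1, 1], [0, 0]])
        h = local_field(small_params, config, 0)
        assert h == pytest.approx(
            local_field(small_params, config.mean(axis=1), 0))

    def test_index_out_of_range(self, small_params):
        with pytest.raises(IndexError):
            local_field(small_params, np.zeros(3), 3)


class TestEnergy:
    def test_all_zero_configuration_has_zero_energy(self, small_params):
        assert energy(np.zeros((3, 2)), small_params) == 0.0

    def test_single_active_neuron_no_couplings(self, decoupled_params):
        config = np.zeros((3, 5))
        config[1, 2] = 1
        assert energy(config, decoupled_params) == pytest.approx(
            -decoupled_params.inputs[1])

    def test_derivative_wrt_input_is_minus_pool_count(self, small_params):
        """dE/dlambda_1 = -n_1, the identity behind the exact Fisher form."""
        config = np.array([[1, 1], [0, 1], [1, 0]])
        eps = 1e-6
        lam = np.array(small_params.inputs)
        p_plus = BinaryNetworkParams(
            n_pops=3, pop_size=2, beta=1.0, w_plus=0.2, w_inh=0.1,
            inputs=(lam[0] + eps, lam[1], lam[2]))
        de = (energy(config, p_plus) - energy(config, small_params)) / eps
        assert de == pytest.approx(-2.0, abs=1e-6)

    def test_shape_mismatch_raises(self, small_params):
        with pytest.raises(InvalidParameterError):
            energy(np.zeros((2, 2)), small_params)


class TestParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_pops=1), dict(pop_size=0), dict(beta=0.0), dict(beta=-1.0),
        dict(w_plus=-0.1), dict(w_inh=-0.1), dict(inputs=(0.0, 0.0)),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n_pops=3, pop_size=2, beta=1.0, w_plus=0.2, w_inh=0.1,
                    inputs=(0.0, 0.0, 0.0))
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            BinaryNetworkParams(**base)

    def test_pair_scaling_off_rescales_population_weights(self):
        p = BinaryNetworkParams(n_pops=2, pop_size=5, beta=1.0, w_plus=0.2,
                                w_inh=0.1, inputs=(0.0, 0.0),
                                pair_scaling=False)
        assert p.effective_w_plus == pytest.approx(0.2 * 4)
        assert p.effective_w_inh == pytest.approx(0.1 * 5)
        assert p.pair_j_exc == pytest.approx(0.2)
        assert p.pair_j_inh == pytest.approx(0.1)
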