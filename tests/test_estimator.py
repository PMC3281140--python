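"""Spike-count Fisher-information estimators against closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from balanced_coding.errors import (
    InvalidParameterError,
    UndefinedStatisticError,
)
from balanced_coding.estimator import (
    CountSample,
    build_histogram,
    fano_factor_counts,
    fisher_empirical,
    fisher_gaussian_form,
    fisher_poisson_form,
    load_count_table,
    moment_curve,
    save_count_table,
)


def gaussian_counts(rng, n, mean, sigma):
    return np.clip(np.round(rng.normal(mean, sigma, n)), 0, None).astype(int)


class TestCountSample:
    def test_rejects_empty_and_negative(self):
        with pytest.raises(InvalidParameterError):
            CountSample(np.array([]))
        with pytest.raises(InvalidParameterError):
            CountSample(np.array([1, -2]))

    def test_roundtrip_through_csv(self, tmp_path):
        rng = np.random.default_rng(0)
        samples = [CountSample(rng.poisson(20, 50), bias_value=b)
                   for b in (-10.0, 0.0, 10.0)]
        path = tmp_path / "counts.csv"
        save_count_table(samples, path)
        loaded = load_count_table(path)
        assert [s.bias_value for s in loaded] == [-10.0, 0.0, 10.0]
        for a, b in zip(samples, loaded):
            assert np.array_equal(a.counts, b.counts)


class TestBuildHistogram:
    def test_point_mass_for_identical_counts(self):
        h = build_histogram(CountSample(np.full(10, 7)))
        assert h.support.tolist() == [7]
        assert h.probabilities.tolist() == [1.0]

    def test_normalized_after_smoothing(self):
        rng = np.random.default_rng(1)
        h = build_histogram(CountSample(rng.poisson(5, 100)),
                            support=np.arange(0, 30), pseudocount=0.5)
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(h.probabilities > 0)

    def test_large_sample_matches_poisson_pmf(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, 100_000)
        h = build_histogram(CountSample(counts))
        pmf = stats.poisson.pmf(h.support, 20)
        tv = 0.5 * (np.abs(h.probabilities - pmf).sum()
                    + (1 - pmf.sum()))  # mass outside the empirical support
        assert tv < 0.01


class TestFisherEmpirical:
    def test_identical_samples_give_zero(self):
        counts = np.random.default_rng(3).poisson(30, 500)
        a = CountSample(counts, bias_value=-10.0)
        b = CountSample(counts, bias_value=10.0)
        assert fisher_empirical(a, b).value == 0.0

    def test_recovers_gaussian_closed_form(self):
        """Counts ~ N(a*b + c, sigma): F = a**2 / sigma**2."""
        rng = np.random.default_rng(4)
        a, sigma, base, delta, n = 1.0, 20.0, 300.0, 10.0, 4000
        sm = CountSample(gaussian_counts(rng, n, base - a * delta, sigma),
                         bias_value=-delta)
        sp = CountSample(gaussian_counts(rng, n, base + a * delta, sigma),
                         bias_value=+delta)
        est = fisher_empirical(sm, sp)
        assert est.value == pytest.approx(a ** 2 / sigma ** 2, rel=0.15)

    def test_recovers_poisson_closed_form(self):
        """Counts ~ Poisson(mu + a*b): F = a**2 / mu at b = 0."""
        rng = np.random.default_rng(5)
        a, mu, delta, n = 1.0, 300.0, 10.0, 4000
        sm = CountSample(rng.poisson(mu - a * delta, n), bias_value=-delta)
        sp = CountSample(rng.poisson(mu + a * delta, n), bias_value=+delta)
        est = fisher_empirical(sm, sp)
        assert est.value == pytest.approx(a ** 2 / mu, rel=0.15)

    def test_bias_step_sensitivity_small(self):
        """Halving delta from 10 to 5 Hz moves the estimate by < 10% on a
        smooth Gaussian family (discretization-error bound)."""
        rng = np.random.default_rng(6)
        a, sigma, base, n = 1.0, 20.0, 300.0, 8000
        vals = {}
        for delta in (10.0, 5.0):
            sm = CountSample(gaussian_counts(rng, n, base - a * delta, sigma),
                             bias_value=-delta)
            sp = CountSample(gaussian_counts(rng, n, base + a * delta, sigma),
                             bias_value=+delta)
            vals[delta] = fisher_empirical(sm, sp).value
        assert vals[5.0] == pytest.approx(vals[10.0], rel=0.10)

    def test_bootstrap_standard_error_brackets_truth(self):
        rng = np.random.default_rng(7)
        a, mu, delta, n = 1.0, 100.0, 10.0, 1000
        sm = CountSample(rng.poisson(mu - a * delta, n), bias_value=-delta)
        sp = CountSample(rng.poisson(mu + a * delta, n), bias_value=+delta)
        est = fisher_empirical(sm, sp, n_bootstrap=100, seed=0)
        assert est.standard_error is not None and est.standard_error > 0
        assert abs(est.value - a ** 2 / mu) < 4 * est.standard_error

    def test_mismatched_conventions_rejected(self):
        a = CountSample(np.array([1, 2, 3]), bias_value=-10.0, window_ms=500)
        b = CountSample(np.array([1, 2, 3]), bias_value=10.0, window_ms=200)
        with pytest.raises(InvalidParameterError):
            fisher_empirical(a, b)


class TestClosedForms:
    def test_poisson_form_scaling(self):
        assert fisher_poisson_form(50.0, 0.0).value == 0.0
        f1 = fisher_poisson_form(50.0, 1.0).value
        f2 = fisher_poisson_form(50.0, 2.0).value
        assert f2 == pytest.approx(4 * f1)

    def test_forms_coincide_when_variance_equals_mean(self):
        for mu, slope in [(20.0, 0.5), (300.0, 1.3)]:
            assert fisher_gaussian_form(slope, mu).value == \
                fisher_poisson_form(mu, slope).value

    def test_invalid_denominators(self):
        with pytest.raises(UndefinedStatisticError):
            fisher_poisson_form(0.0, 1.0)
        with pytest.raises(UndefinedStatisticError):
            fisher_gaussian_form(1.0, -1.0)


class TestMomentCurve:
    def _samples(self, rng, slope, biases, base=200.0, sigma=10.0, n=400):
        return [CountSample(gaussian_counts(rng, n, base + slope * b, sigma),
                            bias_value=b) for b in biases]

    def test_linear_mean_recovers_slope(self):
        rng = np.random.default_rng(8)
        biases = (-10.0, 0.0, 10.0)
        curve = moment_curve(self._samples(rng, 1.5, biases))
        assert curve.derivative[1] == pytest.approx(1.5, abs=0.15)
        assert np.isnan(curve.derivative[0]) and np.isnan(curve.derivative[-1])

    def test_constant_mean_zero_derivative(self):
        rng = np.random.default_rng(9)
        curve = moment_curve(self._samples(rng, 0.0, (-10.0, 0.0, 10.0)))
        assert curve.derivative[1] == pytest.approx(0.0, abs=0.15)

    def test_nonuniform_grid_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(InvalidParameterError):
            moment_curve(self._samples(rng, 1.0, (-10.0, 0.0, 25.0)))


class TestFanoFactor:
    def test_poisson_counts_near_one(self):
        rng = np.random.default_rng(11)
        f = fano_factor_counts(CountSample(rng.poisson(40, 5000)))
        assert f == pytest.approx(1.0, abs=0.06)

    def test_constant_counts_zero(self):
        assert fano_factor_counts(CountSample(np.full(50, 9))) == 0.0

    def test_binomial_thinning_below_one(self):
        rng = np.random.default_rng(12)
        counts = rng.binomial(60, 0.5, 5000)
        assert fano_factor_counts(CountSample(counts)) < 1.0

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            fano_factor_counts(CountSample(np.zeros(10, dtype=int)))
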