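"""Fisher-information estimation from trial-structured spike counts.

The sensitivity of a population's spike count n to a small modulatory input b
(a top-down bias rate, in Hz) is quantified by the Fisher information

    F(b) = E[ (d log P(n | b) / db)**2 ],

whose inverse bounds the variance of any unbiased estimator of b (Cramer-Rao).
Three estimators are provided:

* ``fisher_empirical`` - the definition itself, with P(n|b) replaced by
  empirical count histograms at b - delta and b + delta and the derivative by
  a centered finite difference (default step delta = 10 Hz);
* ``fisher_poisson_form`` - slope**2 / mean, exact for Poisson counts
  (the subthreshold, high-inhibition regime);
* ``fisher_gaussian_form`` - slope**2 / variance, exact for Gaussian counts
  (the suprathreshold, low-inhibition regime); the two coincide whenever
  variance = mean.

Counts may come from the spiking simulator or from any delimited-text table
with columns trial, count, bias_hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedStatisticError

__all__ = [
    "CountSample",
    "CountHistogram",
    "FisherEstimate",
    "CountMomentCurve",
    "build_histogram",
    "fisher_empirical",
    "fisher_poisson_form",
    "fisher_gaussian_form",
    "moment_curve",
    "fano_factor_counts",
    "load_count_table",
    "save_count_table",
]

#: method tags carried by FisherEstimate
METHODS = ("analytic-binary", "exact-binary", "empirical",
           "poisson-form", "gaussian-form")


@dataclass(frozen=True)
class CountSample:
    """Spike counts over trials at one bias value.

    ``aggregation`` records whether each entry is the pool-summed count of one
    trial ("pool-sum", the default observable) or a per-neuron count
    ("per-neuron").
    """

    counts: np.ndarray
    bias_value: float = 0.0
    window_ms: float = 500.0
    aggregation: str = "pool-sum"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.size == 0:
            raise InvalidParameterError("empty count sample")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise InvalidParameterError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_trials(self) -> int:
        return int(self.counts.size)

    def mean(self) -> float:
        return float(self.counts.mean())

    def variance(self) -> float:
        """Unbiased (ddof=1) sample variance of the per-trial counts."""
        return float(self.counts.var(ddof=1))


@dataclass(frozen=True)
class CountHistogram:
    """Normalized relative-frequency histogram of counts on an integer support."""

    support: np.ndarray
    probabilities: np.ndarray
    smoothing: str = "none"
    pseudocount: float = 0.0


@dataclass(frozen=True)
class FisherEstimate:
    """A Fisher-information value and how it was obtained.

    ``value`` is in the bias parameter's inverse-square units (Hz**-2 for the
    spiking pipeline, dimensionless-input**-2 for the binary model).
    """

    value: float
    method: str
    bias_step: float | None = None
    standard_error: float | None = None
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InvalidParameterError("Fisher information must be >= 0")


@dataclass(frozen=True)
class CountMomentCurve:
    """Count mean/variance and the mean's bias-derivative over a bias grid.

    ``derivative`` holds the centered finite difference on interior grid
    points and NaN at the two endpoints.
    """

    bias: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    derivative: np.ndarray

    def interior(self) -> np.ndarray:
        return np.flatnonzero(np.isfinite(self.derivative))


# ---------------------------------------------------------------------------
# histograms and the empirical estimator

def build_histogram(sample: CountSample,
                    support: np.ndarray | None = None,
                    pseudocount: float = 0.0) -> CountHistogram:
    """Relative-frequency histogram, optionally on a shared integer support.

    ``pseudocount`` is added to every bin before normalization so that
    log-probabilities stay finite on bins one sample happens to miss.
    """
    if sample.n_trials < 2:
        raise InvalidParameterError("need at least 2 trials for a histogram")
    if support is None:
        support = np.arange(sample.counts.min(), sample.counts.max() + 1)
    support = np.asarray(support)
    counts = np.bincount(sample.counts - support[0],
                         minlength=support.size).astype(float)
    if counts.size > support.size:
        raise InvalidParameterError("support does not cover the sample")
    counts += pseudocount
    return CountHistogram(
        support=support,
        probabilities=counts / counts.sum(),
        smoothing="pseudocount" if pseudocount else "none",
        pseudocount=pseudocount,
    )


def _union_support(*samples: CountSample) -> np.ndarray:
    lo = min(s.counts.min() for s in samples)
    hi = max(s.counts.max() for s in samples)
    return np.arange(lo, hi + 1)


def _bin_edges(lo: int, hi: int, max_bins: int) -> np.ndarray:
    """Integer bin edges covering [lo, hi] with at most ``max_bins`` bins.

    Wide count supports are coarsened so the per-bin occupancy stays
    reasonable; the plug-in Fisher estimator's noise bias grows with the
    number of occupied bins, and binning at a width well below the count
    standard deviation costs essentially no information.
    """
    span = hi - lo + 1
    width = int(np.ceil(span / max_bins))
    n_bins = int(np.ceil(span / width))
    return lo + width * np.arange(n_bins + 1)


def _fisher_from_counts(counts_minus: np.ndarray, counts_plus: np.ndarray,
                        edges: np.ndarray, delta: float,
                        pseudocount: float, reference: str) -> float:
    def probs(c):
        h = np.histogram(c, bins=edges)[0].astype(float)
        h += pseudocount
        return h / h.sum()

    p_minus = probs(counts_minus)
    p_plus = probs(counts_plus)
    dlogp = (np.log(p_plus) - np.log(p_minus)) / (2.0 * delta)
    if reference == "geometric":
        # log-space midpoint: exact center distribution for exponential
        # families, avoiding the (slope*delta)**2 variance inflation of the
        # arithmetic mixture
        ref = np.sqrt(p_plus * p_minus)
        ref = ref / ref.sum()
    elif reference == "midpoint":
        ref = 0.5 * (p_plus + p_minus)
    elif reference == "minus":
        ref = p_minus
    elif reference == "plus":
        ref = p_plus
    else:
        raise InvalidParameterError(f"unknown reference measure {reference!r}")
    return float(np.sum(ref * dlogp ** 2))


def fisher_empirical(sample_minus: CountSample,
                     sample_plus: CountSample,
                     delta: float | None = None,
                     pseudocount: float = 0.5,
                     reference: str = "geometric",
                     max_bins: int = 30,
                     n_bootstrap: int = 0,
                     seed: int | None = None) -> FisherEstimate:
    """Histogram / finite-difference Fisher information at the midpoint bias.

    The two samples must sit at biases b -+ delta; ``delta`` defaults to half
    their bias separation.  The log-probability derivative is the centered
    difference of the two log-histograms on their (at most ``max_bins``-bin)
    union support, and the expectation of its square is taken under the
    normalized geometric mean of the two histograms by default (the log-space
    midpoint, which for exponential-family counts is the center-bias
    distribution itself; the arithmetic "midpoint" mixture is also available
    but overestimates by a factor ~1 + (slope*delta)**2/variance).  A
    trial-resampling bootstrap (``n_bootstrap`` replicates) yields an
    optional standard error.
    """
    if sample_minus.window_ms != sample_plus.window_ms or \
            sample_minus.aggregation != sample_plus.aggregation:
        raise InvalidParameterError(
            "samples must share the count window and aggregation convention"
        )
    if delta is None:
        delta = 0.5 * (sample_plus.bias_value - sample_minus.bias_value)
    if delta <= 0:
        raise InvalidParameterError("delta must be > 0")
    if pseudocount == 0.0:
        lo = max(sample_minus.counts.min(), sample_plus.counts.min())
        hi = min(sample_minus.counts.max(), sample_plus.counts.max())
        if lo > hi:
            raise InvalidParameterError(
                "count supports are disjoint and no smoothing is applied; "
                "use a pseudocount > 0 or more trials"
            )
    lo = int(min(sample_minus.counts.min(), sample_plus.counts.min()))
    hi = int(max(sample_minus.counts.max(), sample_plus.counts.max()))
    edges = _bin_edges(lo, hi, max_bins)
    value = _fisher_from_counts(sample_minus.counts, sample_plus.counts,
                                edges, delta, pseudocount, reference)
    se = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_bootstrap)
        for k in range(n_bootstrap):
            cm = rng.choice(sample_minus.counts, sample_minus.n_trials)
            cp = rng.choice(sample_plus.counts, sample_plus.n_trials)
            reps[k] = _fisher_from_counts(cm, cp, edges, delta,
                                          pseudocount, reference)
        se = float(reps.std(ddof=1))
    return FisherEstimate(value=value, method="empirical",
                          bias_step=float(delta), standard_error=se)


# ---------------------------------------------------------------------------
# closed forms

def fisher_poisson_form(mean_count: float, mean_slope: float) -> FisherEstimate:
    """Poisson-regime Fisher information: (d<n>/db)**2 / <n>."""
    if mean_count <= 0:
        raise UndefinedStatisticError("Poisson form requires mean_count > 0")
    return FisherEstimate(value=mean_slope ** 2 / mean_count,
                          method="poisson-form")


def fisher_gaussian_form(mean_slope: float, count_variance: float) -> FisherEstimate:
    """Gaussian-regime Fisher information: (d<n>/db)**2 / Var(n).

    Structurally identical to the Poisson form with variance in place of the
    mean, so the two coincide exactly for Poisson-dispersed counts.
    """
    if count_variance <= 0:
        raise UndefinedStatisticError("Gaussian form requires count_variance > 0")
    return FisherEstimate(value=mean_slope ** 2 / count_variance,
                          method="gaussian-form")


# ---------------------------------------------------------------------------
# moment curves and the Fano factor

def moment_curve(samples: Sequence[CountSample]) -> CountMomentCurve:
    """Mean, variance and centered-difference mean slope over a uniform bias grid."""
    if len(samples) < 3:
        raise InvalidParameterError("need >= 3 bias grid points")
    order = np.argsort([s.bias_value for s in samples])
    samples = [samples[i] for i in order]
    bias = np.array([s.bias_value for s in samples], dtype=float)
    steps = np.diff(bias)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12) or steps[0] <= 0:
        raise InvalidParameterError("bias grid must be uniform and strictly increasing")
    mean = np.array([s.mean() for s in samples])
    var = np.array([s.variance() for s in samples])
    deriv = np.full(bias.size, np.nan)
    deriv[1:-1] = (mean[2:] - mean[:-2]) / (bias[2:] - bias[:-2])
    return CountMomentCurve(bias=bias, mean=mean, variance=var, derivative=deriv)


def fano_factor_counts(sample: CountSample) -> float:
    """Trial-to-trial Fano factor of the counts: variance / mean (ddof=1)."""
    mu = sample.mean()
    if mu == 0:
        raise UndefinedStatisticError("Fano factor undefined: zero mean count")
    return sample.variance() / mu


# ---------------------------------------------------------------------------
# delimited-text interchange

def load_count_table(path: str | Path,
                     window_ms: float = 500.0,
                     aggregation: str = "pool-sum") -> list[CountSample]:
    """Read a CSV with columns trial, count, bias_hz into per-bias samples."""
    df = pd.read_csv(path)
    required = {"trial", "count", "bias_hz"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"count table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for bias, grp in df.groupby("bias_hz", sort=True):
        counts = grp.sort_values("trial")["count"].to_numpy()
        out.append(CountSample(counts=counts, bias_value=float(bias),
                               window_ms=window_ms, aggregation=aggregation))
    return out


def save_count_table(samples: Sequence[CountSample], path: str | Path) -> None:
    """Write per-bias samples as a CSV with columns trial, count, bias_hz."""
    frames = [
        pd.DataFrame({
            "trial": np.arange(s.n_trials),
            "count": s.counts,
            "bias_hz": s.bias_value,
        })
        for s in samples
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
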