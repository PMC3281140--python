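"""Mean-field analysis of the binary network.

Replacing neighbor states by their population means closes the dynamics into
n_pops coupled fixed-point equations

    m_p = sigma(beta * (w+ m_p - wI * sum_q m_q + lambda_p))        (global inhibition)

solved here by damped fixed-point iteration.  From the converged activities
follow the factorized population moments (variance N m (1-m), Fano factor
1 - m), the closed-form Fisher information of the network state with respect
to the population-1 input,

    F = N beta**2 m_1 (1 - m_1),

and the balance condition: F is maximal over the inhibition level exactly
where the total population-1 input vanishes (m_1 = 1/2), i.e. where the
excitatory and inhibitory synaptic currents cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from ..errors import ConvergenceError, InvalidParameterError, NoRootError, \
    UndefinedStatisticError
from .model import BinaryNetworkParams

__all__ = [
    "MeanFieldSolution",
    "PopulationMoments",
    "mean_field_solve",
    "population_moments",
    "fano_reduction",
    "fisher_analytic",
    "balance_condition",
    "balance_residual",
]


@dataclass(frozen=True)
class MeanFieldSolution:
    """Converged (or flagged) solution of the mean-field fixed-point equations."""

    m: np.ndarray
    converged: bool
    iterations: int
    residual: float
    params: BinaryNetworkParams


@dataclass(frozen=True)
class PopulationMoments:
    """Factorized mean-field moments of one population's summed activity."""

    mean: float
    second_moment: float
    variance: float
    fano: float


def _fields(params: BinaryNetworkParams, m: np.ndarray) -> np.ndarray:
    inh = m.sum() if params.inhibit_within else m.sum() - m
    return (params.effective_w_plus * m
            - params.effective_w_inh * inh
            + params.external_field)


def mean_field_solve(params: BinaryNetworkParams,
                     init: np.ndarray | None = None,
                     tol: float = 1e-10,
                     max_iter: int = 10_000,
                     damping: float = 0.5) -> MeanFieldSolution:
    """Damped fixed-point iteration for the mean population activities.

    Starts from the decoupled solution sigma(beta * lambda) unless ``init`` is
    given, which selects the branch continuously connected to the symmetric /
    decoupled state in multistable regimes.  Non-convergence is flagged in the
    result, not raised.
    """
    if tol <= 0:
        raise InvalidParameterError("tol must be > 0")
    if not 0 < damping <= 1:
        raise InvalidParameterError("damping must be in (0, 1]")
    if init is None:
        m0 = expit(params.beta * params.external_field)
    else:
        m0 = np.asarray(init, dtype=float).copy()
        if m0.shape != (params.n_pops,) or np.any((m0 < 0) | (m0 > 1)):
            raise InvalidParameterError("init must be n_pops activities in [0, 1]")
    residual = np.inf
    total_it = 0
    m = m0
    # strong inhibition can make the damped map oscillatory; retry with
    # progressively heavier damping before declaring failure
    for damp in (damping, damping / 5.0, damping / 25.0):
        m = m0.copy()
        for _ in range(1, max_iter + 1):
            total_it += 1
            target = expit(params.beta * _fields(params, m))
            residual = float(np.max(np.abs(target - m)))
            if residual < tol:
                m = target
                break
            m = damp * target + (1.0 - damp) * m
        if residual < tol:
            break
    return MeanFieldSolution(
        m=m, converged=residual < tol, iterations=total_it,
        residual=residual, params=params,
    )


def _require_converged(solution: MeanFieldSolution) -> None:
    if not solution.converged:
        raise ConvergenceError(
            f"mean-field solver did not converge "
            f"(residual {solution.residual:.2e} after {solution.iterations} iters)"
        )


def population_moments(solution: MeanFieldSolution,
                       params: BinaryNetworkParams,
                       pop: int) -> PopulationMoments:
    """Moments of the summed activity n_pop under the factorized mean field.

    mean = N m, second moment = N m + N (N-1) m**2, variance = N m (1-m),
    Fano factor = variance / mean = 1 - m.  Raises if the mean vanishes.
    """
    _require_converged(solution)
    if not 0 <= pop < params.n_pops:
        raise IndexError(f"population index {pop} out of range")
    m = float(solution.m[pop])
    n = params.pop_size
    mean = n * m
    second = n * m + n * (n - 1) * m ** 2
    variance = n * m * (1.0 - m)
    if mean == 0.0:
        raise UndefinedStatisticError("Fano factor undefined: mean activity is 0")
    return PopulationMoments(mean=mean, second_moment=second,
                             variance=variance, fano=variance / mean)


def fano_reduction(params: BinaryNetworkParams, bias: float) -> float:
    """Bias-induced reduction of the population-1 Fano factor.

    Defined as Fano(bias=0) - Fano(bias), so a positive value means the
    top-down input reduced the trial-to-trial variability, as observed for
    attended stimuli.
    """
    if bias < 0:
        raise InvalidParameterError("bias must be >= 0")
    base = params.with_bias(0.0)
    biased = params.with_bias(bias)
    f0 = population_moments(mean_field_solve(base), base, 0).fano
    fb = population_moments(mean_field_solve(biased), biased, 0).fano
    return f0 - fb


def fisher_analytic(params: BinaryNetworkParams,
                    solution: MeanFieldSolution | None = None):
    """Closed-form mean-field Fisher information w.r.t. the population-1 input.

    F = N beta**2 m_1 (1 - m_1) evaluated at the fixed point: the summed
    population-1 activity is a sum of N conditionally independent Bernoulli(m_1)
    units whose parameter responds to lambda_1 with gain beta m_1 (1 - m_1).
    """
    from ..estimator import FisherEstimate

    if solution is None:
        solution = mean_field_solve(params)
    _require_converged(solution)
    m1 = float(solution.m[0])
    value = params.pop_size * params.beta ** 2 * m1 * (1.0 - m1)
    return FisherEstimate(value=value, method="analytic-binary")


def balance_residual(params: BinaryNetworkParams) -> float:
    """Total population-1 input at the mean-field fixed point.

    Positive when recurrent + external excitation exceeds inhibition; zero at
    the balanced point, where m_1 = 1/2 and the Fisher information is maximal.
    """
    sol = mean_field_solve(params)
    _require_converged(sol)
    return float(_fields(params, sol.m)[0])


def balance_condition(params: BinaryNetworkParams,
                      bracket: tuple[float, float] = (0.0, 10.0),
                      xtol: float = 1e-12) -> float:
    """Inhibition level w_inh* at which population-1 inputs balance.

    Solves balance_residual(w_inh) = 0 by Brent root finding on ``bracket``;
    the bracket is expanded once (doubled) if the residual does not change
    sign.  At low cohesion this root is unique and coincides with the argmax
    of :func:`fisher_analytic` over the inhibition level.
    """
    f = lambda w: balance_residual(params.with_w_inh(w))
    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        hi2 = hi + (hi - lo)
        fhi2 = f(hi2)
        if flo * fhi2 > 0:
            raise NoRootError(
                f"no sign change of the balance residual in [{lo}, {hi2}] "
                f"(f({lo})={flo:.3g}, f({hi2})={fhi2:.3g})"
            )
        hi, fhi = hi2, fhi2
    return float(brentq(f, lo, hi, xtol=xtol))
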