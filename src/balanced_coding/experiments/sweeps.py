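"""Inhibition-level sweeps reproducing the central result surfaces.

Three surfaces are produced, at desk scale by default:

* binary model (all analytic): balance residual, Fano-factor reduction and
  Fisher information vs the inhibition level, with the balance root and both
  argmaxima — the Fisher peak sits exactly at balance, the Fano-reduction
  peak nearby;
* spiking model, currents + empirical Fisher information: the empirical
  Fisher peak co-locates with the zero crossing of (mean synaptic current -
  threshold current);
* spiking model, count moments: mean count, its bias-derivative, count
  variance, and the slope**2/variance analytic fit tracking the empirical
  Fisher information.

All randomness flows from ``SweepSpec.master_seed`` through per-(grid point,
bias, trial) seed derivations, so any single grid point can be re-run in
isolation with an identical result.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ..binary import (
    BinaryNetworkParams,
    balance_condition,
    balance_residual,
    fano_reduction,
    fisher_analytic,
    mean_field_solve,
    population_moments,
)
from ..errors import InvalidParameterError
from ..estimator import (
    CountSample,
    fisher_empirical,
    fisher_gaussian_form,
    fisher_poisson_form,
    moment_curve,
)
from ..spiking import (
    ArchitectureParams,
    StimulusProtocol,
    build_network,
    run_trials,
)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_binary_sweep",
    "run_fisher_current_sweep",
    "run_moment_fit_sweep",
    "run_spiking_sweep",
    "verify_fano_fisher_coincidence",
    "PEAK_TOL_STEPS",
    "FANO_FISHER_TOL_STEPS",
    "FIT_BAND_SE",
    "FIT_FRACTION",
]

#: peak co-location tolerance, in grid steps ("peaks around" is read as
#: within one step of the swept grid)
PEAK_TOL_STEPS = 1
#: Fano-reduction vs Fisher peak separation tolerance on a 100-point grid
#: (the reduction peak is only asymptotically, bias -> 0, at the Fisher peak)
FANO_FISHER_TOL_STEPS = 3
#: "within bootstrap error" band, in bootstrap standard errors (95% band)
FIT_BAND_SE = 2.0
#: fraction of grid points at which the analytic fit must fall in the band
FIT_FRACTION = 0.8


@dataclass(frozen=True)
class SweepSpec:
    """Grid, trial counts, scale and seed of one sweep."""

    w_inh_grid: np.ndarray
    n_trials: int = 200
    scale: float = 0.25
    master_seed: int = 0
    delta_hz: float = 10.0
    bias_centers: tuple[float, ...] = (0.0,)
    bias: float = 0.1          # binary-model bias for the Fano reduction
    dt: float = 0.05
    n_bootstrap: int = 200
    out_dir: str | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.w_inh_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise InvalidParameterError("w_inh_grid must be strictly increasing")
        object.__setattr__(self, "w_inh_grid", grid)
        if self.n_trials < 2:
            raise InvalidParameterError("n_trials must be >= 2")
        if not 0 < self.scale <= 1:
            raise InvalidParameterError("scale must be in (0, 1]")

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.w_inh_grid)))

    def point_seed(self, i_grid: int, i_bias: int) -> int:
        """Documented seed derivation: one sub-seed per (grid point, bias)."""
        ss = np.random.SeedSequence(
            entropy=int(self.master_seed) % (2 ** 31),
            spawn_key=(i_grid, i_bias),
        )
        return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class SweepResult:
    """A sweep table plus metadata (seeds, argmaxima, provenance hash)."""

    table: pd.DataFrame
    meta: dict

    def save(self, out_dir: str | Path, stem: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / f"{stem}.csv", index=False)
        with open(out / f"{stem}.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)


def _provenance(**kwargs) -> dict:
    blob = json.dumps({k: str(v) for k, v in sorted(kwargs.items())})
    return {"config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            **kwargs}


# ---------------------------------------------------------------------------
# binary model (all analytic)

def run_binary_sweep(params: BinaryNetworkParams, sweep: SweepSpec) -> SweepResult:
    """Analytic sweep of the binary network over the inhibition level.

    Per grid point: balance residual, population-1 Fano factor, Fano-factor
    reduction at ``sweep.bias``, and the closed-form Fisher information at the
    params' own bias.  Metadata records the balance root and both argmaxima.
    Purely deterministic.
    """
    rows = []
    for w in sweep.w_inh_grid:
        p = params.with_w_inh(float(w))
        sol = mean_field_solve(p)
        row = {
            "w_inh": float(w),
            "converged": sol.converged,
            "balance_residual": balance_residual(p),
            "m1": float(sol.m[0]),
            "fano": population_moments(sol, p, 0).fano if sol.converged
            else np.nan,
            "fano_reduction": fano_reduction(p, sweep.bias),
            "fisher_analytic": fisher_analytic(p, sol).value,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    root = balance_condition(
        params,
        bracket=(float(sweep.w_inh_grid[0]), float(sweep.w_inh_grid[-1])),
    )
    meta = _provenance(
        kind="binary-inhibition-sweep", params=params, bias=sweep.bias,
        grid=[float(sweep.w_inh_grid[0]), float(sweep.w_inh_grid[-1]),
              int(sweep.w_inh_grid.size)],
    )
    meta.update(
        balance_root=root,
        argmax_fisher=float(table.w_inh[table.fisher_analytic.idxmax()]),
        argmax_fano_reduction=float(table.w_inh[table.fano_reduction.idxmax()]),
        grid_step=sweep.grid_step,
    )
    result = SweepResult(table, meta)
    if sweep.out_dir:
        result.save(sweep.out_dir, "binary_sweep")
    return result


def verify_fano_fisher_coincidence(
        params: BinaryNetworkParams,
        sweep: SweepSpec,
        biases: Sequence[float] = (0.3, 0.1, 0.05)) -> dict:
    """Numerical check that the Fano-reduction peak tracks the Fisher peak.

    Locates both maxima continuously (bounded scalar minimization over the
    sweep interval) for several bias magnitudes and reports their separation:
    it must stay within FANO_FISHER_TOL_STEPS of a 100-point grid for small
    biases and shrink as the bias decreases.  Deterministic.
    """
    lo, hi = float(sweep.w_inh_grid[0]), float(sweep.w_inh_grid[-1])
    step_100 = (hi - lo) / 99.0

    def argmax(fun) -> float:
        res = minimize_scalar(lambda w: -fun(w), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": step_100 * 1e-3})
        return float(res.x)

    w_fisher = argmax(
        lambda w: fisher_analytic(params.with_w_inh(w)).value)
    report = {
        "argmax_fisher": w_fisher,
        "balance_root": balance_condition(params, bracket=(lo, hi)),
        "grid_step_100": step_100,
        "biases": list(biases),
        "separations": [],
    }
    for b in sorted(biases, reverse=True):
        w_fano = argmax(lambda w: fano_reduction(params.with_w_inh(w), b))
        report["separations"].append(abs(w_fano - w_fisher))
    seps = report["separations"]  # ordered by decreasing bias
    report["separation_shrinks_with_bias"] = all(
        s2 <= s1 + 1e-9 for s1, s2 in zip(seps, seps[1:]))
    report["smallest_bias_separation_steps"] = seps[-1] / step_100
    report["within_tolerance"] = seps[-1] <= FANO_FISHER_TOL_STEPS * step_100
    return report


# ---------------------------------------------------------------------------
# spiking model

def run_spiking_sweep(arch: ArchitectureParams,
                      protocol: StimulusProtocol,
                      sweep: SweepSpec,
                      window_ms: tuple[float, float] | None = None) -> SweepResult:
    """Simulate the inhibition-level sweep and estimate everything at once.

    Per grid point w_I, trials are run at every bias in the union of
    {c - delta, c, c + delta} over ``sweep.bias_centers``; from those counts
    the empirical Fisher information (per center, with bootstrap SE), the
    count-moment curve and the Poisson/Gaussian closed forms are computed, and
    the pool-1 current balance (mean synaptic current - threshold current) is
    measured on the zero-extra-bias trials.
    """
    delta = sweep.delta_hz
    biases = sorted({round(c + s * delta, 9)
                     for c in sweep.bias_centers for s in (-1.0, 0.0, 1.0)})
    rows = []
    for i, w in enumerate(sweep.w_inh_grid):
        net = build_network(arch.with_w_inh(float(w)), scale=sweep.scale)
        samples: dict[float, CountSample] = {}
        current_balance = np.nan
        for j, b in enumerate(biases):
            counts, exc_na, inh_na = run_trials(
                net, protocol.with_bias(b), sweep.n_trials,
                dt=sweep.dt, seed=sweep.point_seed(i, j),
                pool=0, window_ms=window_ms,
                record_currents=(b == 0.0),
            )
            win = window_ms or (protocol.stabilization_ms,
                                min(protocol.stabilization_ms + 500.0,
                                    protocol.duration_ms))
            samples[b] = CountSample(
                counts=counts, bias_value=b, window_ms=win[1] - win[0])
            if b == 0.0:
                current_balance = (exc_na + inh_na
                                   - net.exc_params.threshold_current)
        row = {"w_inh": float(w), "current_balance_nA": current_balance}
        curve = moment_curve([samples[b] for b in biases]) \
            if len(biases) >= 3 else None
        for c in sweep.bias_centers:
            est = fisher_empirical(
                samples[round(c - delta, 9)], samples[round(c + delta, 9)],
                delta=delta, n_bootstrap=sweep.n_bootstrap,
                seed=sweep.point_seed(i, 101),
            )
            tag = "" if len(sweep.bias_centers) == 1 else f"_b{c:g}"
            row[f"fisher_empirical{tag}"] = est.value
            row[f"fisher_se{tag}"] = est.standard_error
        center = sweep.bias_centers[0]
        s_c = samples[round(center, 9)]
        slope = (samples[round(center + delta, 9)].mean()
                 - samples[round(center - delta, 9)].mean()) / (2 * delta)
        row.update(
            mean_count=s_c.mean(),
            count_variance=s_c.variance(),
            mean_slope=slope,
            fano=s_c.variance() / s_c.mean() if s_c.mean() > 0 else np.nan,
            fisher_gaussian_form=(fisher_gaussian_form(slope, s_c.variance())
                                  .value if s_c.variance() > 0 else np.nan),
            fisher_poisson_form=(fisher_poisson_form(s_c.mean(), slope).value
                                 if s_c.mean() > 0 else np.nan),
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    meta = _provenance(
        kind="spiking-inhibition-sweep", arch=arch, protocol=protocol,
        scale=sweep.scale, n_trials=sweep.n_trials, dt=sweep.dt,
        master_seed=sweep.master_seed, delta_hz=sweep.delta_hz,
        bias_centers=list(sweep.bias_centers),
    )
    fi = table["fisher_empirical"] if "fisher_empirical" in table else \
        table[[c for c in table.columns if c.startswith("fisher_empirical")][0]]
    meta.update(
        argmax_fisher_empirical=float(table.w_inh[fi.idxmax()]),
        zero_crossing_w_inh=_zero_crossing(table.w_inh.to_numpy(),
                                           table.current_balance_nA.to_numpy()),
        grid_step=sweep.grid_step,
    )
    return SweepResult(table, meta)


def _zero_crossing(x: np.ndarray, y: np.ndarray) -> float:
    """Linear-interpolated first downward zero crossing of y(x); NaN if none."""
    for k in range(y.size - 1):
        if y[k] >= 0 >= y[k + 1]:
            if y[k] == y[k + 1]:
                return float(x[k])
            return float(x[k] - y[k] * (x[k + 1] - x[k]) / (y[k + 1] - y[k]))
    return float("nan")


def run_fisher_current_sweep(arch: ArchitectureParams,
             protocol: StimulusProtocol,
             sweep: SweepSpec,
             window_ms: tuple[float, float] | None = None) -> SweepResult:
    """Current balance and empirical Fisher information vs inhibition level."""
    res = run_spiking_sweep(arch, protocol, sweep, window_ms=window_ms)
    if sweep.out_dir:
        res.save(sweep.out_dir, "fisher_current_sweep")
    return res


def run_moment_fit_sweep(arch: ArchitectureParams,
             protocol: StimulusProtocol,
             sweep: SweepSpec,
             window_ms: tuple[float, float] | None = None) -> SweepResult:
    """Count moments, empirical Fisher information and its analytic fit.

    Adds the fit check: at which grid points the slope**2/variance form lies
    within FIT_BAND_SE bootstrap standard errors of the empirical estimate.
    """
    res = run_spiking_sweep(arch, protocol, sweep, window_ms=window_ms)
    t = res.table
    se = t["fisher_se"] if "fisher_se" in t else None
    if se is not None:
        ok = (np.abs(t.fisher_gaussian_form - t.fisher_empirical)
              <= FIT_BAND_SE * se)
        res.meta["fit_within_band_fraction"] = float(ok.mean())
        res.meta["fit_ok"] = bool(ok.mean() >= FIT_FRACTION)
    slope_ratio = (t.mean_slope ** 2 / t.count_variance).to_numpy()
    res.meta["argmax_slope_ratio"] = float(t.w_inh[int(np.argmax(slope_ratio))])
    if sweep.out_dir:
        res.save(sweep.out_dir, "moment_fit_sweep")
    return res
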