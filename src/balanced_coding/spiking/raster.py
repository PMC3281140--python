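"""Spike rasters, current records, counting and delimited-text I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError
from .params import NeuronParams

__all__ = [
    "SpikeRaster",
    "CurrentRecord",
    "pool_spike_counts",
    "counts_from_rasters",
    "mean_current_vs_threshold",
    "save_rasters_csv",
    "load_rasters_csv",
    "save_currents_csv",
]


@dataclass(frozen=True)
class SpikeRaster:
    """Spike events of one trial: parallel (times, neurons) arrays plus the
    neuron -> pool membership map."""

    trial: int
    times: np.ndarray      # ms
    neurons: np.ndarray    # neuron ids
    pool_of: np.ndarray    # pool id per neuron
    duration_ms: float

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isi_by_neuron(self) -> dict[int, np.ndarray]:
        """Inter-spike intervals per neuron (for refractory checks)."""
        out = {}
        order = np.lexsort((self.times, self.neurons))
        nrn = self.neurons[order]
        t = self.times[order]
        for i in np.unique(nrn):
            ti = t[nrn == i]
            if ti.size > 1:
                out[int(i)] = np.diff(ti)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": self.trial,
            "neuron": self.neurons,
            "time_ms": self.times,
            "pool": self.pool_of[self.neurons],
        })


@dataclass(frozen=True)
class CurrentRecord:
    """Pool-mean synaptic drive vs time, split into excitatory (>= 0 toward
    the excitatory reversal) and inhibitory (<= 0) components, in nA."""

    time_ms: np.ndarray
    excitatory: np.ndarray  # (n_steps, n_pools)
    inhibitory: np.ndarray  # (n_steps, n_pools)
    threshold_current: float  # nA, g_L (V_thr - V_L) of the excitatory cells

    @property
    def total(self) -> np.ndarray:
        return self.excitatory + self.inhibitory

    def to_dataframe(self) -> pd.DataFrame:
        n_steps, n_pools = self.excitatory.shape
        frames = []
        for p in range(n_pools):
            frames.append(pd.DataFrame({
                "time_ms": self.time_ms,
                "pool": p,
                "mean_current_nA": self.total[:, p],
                "excitatory_nA": self.excitatory[:, p],
                "inhibitory_nA": self.inhibitory[:, p],
            }))
        return pd.concat(frames, ignore_index=True)


def pool_spike_counts(raster: SpikeRaster,
                      pool: int,
                      window_ms: tuple[float, float]) -> np.ndarray:
    """Per-neuron spike counts of one pool inside a time window.

    Returns an integer array over the pool's neurons (sum it for the pooled
    population count).  Event order in the raster is irrelevant.
    """
    if pool < 0 or pool >= int(raster.pool_of.max()) + 1:
        raise InvalidParameterError(f"unknown pool {pool}")
    t0, t1 = window_ms
    members = np.flatnonzero(raster.pool_of == pool)
    if raster.n_spikes == 0:
        return np.zeros(members.size, dtype=np.int64)
    in_window = (raster.times >= t0) & (raster.times < t1)
    nrn = raster.neurons[in_window]
    idx = np.searchsorted(members, nrn)
    sel = (idx < members.size)
    sel &= members[np.clip(idx, 0, members.size - 1)] == nrn
    return np.bincount(idx[sel], minlength=members.size).astype(np.int64)


def counts_from_rasters(rasters: Sequence[SpikeRaster],
                        pool: int,
                        window_ms: tuple[float, float],
                        bias_value: float = 0.0,
                        aggregate: str = "pool-sum"):
    """Collect per-trial counts from rasters into an estimator CountSample."""
    from ..estimator import CountSample

    if aggregate == "pool-sum":
        counts = [pool_spike_counts(r, pool, window_ms).sum() for r in rasters]
    elif aggregate == "per-neuron":
        counts = np.concatenate(
            [pool_spike_counts(r, pool, window_ms) for r in rasters])
    else:
        raise InvalidParameterError(f"unknown aggregation {aggregate!r}")
    return CountSample(counts=np.asarray(counts), bias_value=bias_value,
                       window_ms=window_ms[1] - window_ms[0],
                       aggregation=aggregate)


def mean_current_vs_threshold(record: CurrentRecord,
                              neuron_params: NeuronParams | None = None,
                              window_ms: tuple[float, float] | None = None,
                              pool: int = 0) -> float:
    """Time-averaged pool mean synaptic current minus the threshold current (nA).

    The threshold current g_L (V_thr - V_L) is the constant current that holds
    a leak-only neuron exactly at threshold; zero marks the operational
    excitation-inhibition balance point.  Positive values mean suprathreshold
    drive.
    """
    if record.time_ms.size == 0:
        raise InvalidParameterError("empty current record")
    i_thr = (neuron_params.threshold_current if neuron_params is not None
             else record.threshold_current)
    if window_ms is None:
        sel = slice(None)
    else:
        sel = (record.time_ms >= window_ms[0]) & (record.time_ms < window_ms[1])
        if not np.any(sel):
            raise InvalidParameterError("window outside the recorded interval")
    return float(record.total[sel, pool].mean() - i_thr)


# ---------------------------------------------------------------------------
# delimited-text I/O

def save_rasters_csv(rasters: Sequence[SpikeRaster], path: str | Path) -> None:
    """CSV with columns trial, neuron, time_ms, pool."""
    pd.concat([r.to_dataframe() for r in rasters],
              ignore_index=True).to_csv(path, index=False)


def load_rasters_csv(path: str | Path,
                     pool_of: np.ndarray,
                     duration_ms: float) -> list[SpikeRaster]:
    df = pd.read_csv(path)
    out = []
    for trial, grp in df.groupby("trial", sort=True):
        out.append(SpikeRaster(
            trial=int(trial),
            times=grp["time_ms"].to_numpy(float),
            neurons=grp["neuron"].to_numpy(np.int64),
            pool_of=np.asarray(pool_of),
            duration_ms=duration_ms,
        ))
    return out


def save_currents_csv(record: CurrentRecord, path: str | Path) -> None:
    """CSV with columns time_ms, pool, mean_current_nA, excitatory_nA,
    inhibitory_nA."""
    record.to_dataframe().to_csv(path, index=False)
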