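"""Fluctuating external background rate.

Every neuron receives an independent external Poisson train whose rate is
shared within its population and fluctuates around the nominal total
background rate nu_0 as a mean-reverting Ornstein-Uhlenbeck process

    tau_n dnu/dt = -(nu - nu_0) + sigma sqrt(2 tau_n) eta(t),

sampled exactly at the integration step; the stationary law is
N(nu_0, sigma**2).  Negative excursions are rectified to zero at emission
(the underlying state is left unrectified, so the rectification bias on the
long-run mean stays mild for sigma << nu_0).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from ..errors import InvalidParameterError
from .params import StimulusProtocol

__all__ = ["background_rate_process"]


def background_rate_process(protocol: StimulusProtocol,
                            dt: float,
                            duration: float,
                            n_pools: int,
                            nominal_rate: float,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Rectified OU rate series, shape (n_steps, n_pools), in Hz.

    Pools receive independent realizations started from the stationary law.
    With ``noise_sigma`` = 0 the series is constantly ``nominal_rate``.
    """
    if dt <= 0 or duration <= 0:
        raise InvalidParameterError("dt and duration must be > 0")
    n_steps = int(round(duration / dt))
    if protocol.noise_sigma == 0:
        return np.full((n_steps, n_pools), float(nominal_rate))
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rho = np.exp(-dt / protocol.noise_tau)
    innovation = protocol.noise_sigma * np.sqrt(1.0 - rho ** 2)
    # AR(1) recursion x_t = rho x_{t-1} + innovation*xi_t as an IIR filter
    xi = rng.standard_normal((n_steps, n_pools))
    x0 = rng.standard_normal(n_pools) * protocol.noise_sigma
    dev = lfilter([1.0], [1.0, -rho], innovation * xi, axis=0,
                  zi=(rho * x0)[None, :])[0]
    return np.clip(nominal_rate + dev, 0.0, None)
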