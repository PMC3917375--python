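"""Stochastic CheY-P concentration dynamics.

CheY-P fluctuations are modeled as a discretized Ornstein-Uhlenbeck
process,

    Y(t+dt) = Y(t) - (Y(t) - <Y>)/tau * dt + A * xi,   xi ~ N(0, 1),

with amplitude A set by the noise mode (see
``params.FluctuationParams``).  The instantaneous CW bias follows a
steep Hill function of Y, and candidate traces are accepted only when
their mean CW bias falls in a target band — the observation-matched
rejection step used before driving the flagellar motors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .params import FluctuationParams, HillParams, ParameterError


class TraceAcceptanceError(RuntimeError):
    """Rejection loop exhausted its attempt cap.

    Carries the mean-CW-bias values of the rejected attempts so callers
    can see how far the ensemble sits from the target band.
    """

    def __init__(self, message: str, attempted_means: Sequence[float]):
        super().__init__(message)
        self.attempted_means = tuple(attempted_means)


@dataclass
class CheYTrace:
    """A CheY-P concentration time series at resolution dt."""

    values: np.ndarray
    dt: float
    seed: Optional[int] = None

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_chey_trace(
    params: FluctuationParams,
    duration: float,
    seed=None,
    burn_in: float = 0.0,
) -> CheYTrace:
    """Simulate one OU CheY-P trace of the given duration.

    Starts at Y(0) = <Y> (the process mixes within ~tau, short against
    the trace lengths used; an optional ``burn_in`` discards an initial
    stretch).  Values are clipped at zero: concentrations are physical.
    The recursion is a linear AR(1) scan, evaluated with
    ``scipy.signal.lfilter``.
    """
    if duration < params.dt:
        raise ParameterError("duration must be at least one step")
    rng = _as_rng(seed)
    n = int(round((duration + burn_in) / params.dt))
    n_burn = int(round(burn_in / params.dt))
    a = 1.0 - params.dt / params.tau
    drive = (params.dt / params.tau) * params.y_mean + params.step_amplitude * rng.standard_normal(n)
    # y[t] = a*y[t-1] + drive[t], with y[-1] = y_mean
    y = lfilter([1.0], [1.0, -a], drive, zi=[a * params.y_mean])[0]
    np.clip(y, 0.0, None, out=y)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return CheYTrace(values=y[n_burn:], dt=params.dt, seed=seed_val)


def hill_cw_bias(y, params: HillParams):
    """Instantaneous CW bias for CheY-P concentration ``y`` (µM).

    Strictly increasing, in [0, 1); cb = 0.5 at y = kd.  Vectorized.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ParameterError("concentration must be >= 0")
    with np.errstate(over="ignore"):
        ratio = (y_arr / params.kd) ** params.h
        out = np.where(np.isinf(ratio), 1.0, ratio / (1.0 + ratio))
    return float(out) if np.isscalar(y) else out


def hill_inverse(cb: float, params: HillParams) -> float:
    """Concentration at which the Hill map yields CW bias ``cb``."""
    if not (0 < cb < 1):
        raise ParameterError("cb must lie in (0, 1) for inversion")
    return params.kd * (cb / (1.0 - cb)) ** (1.0 / params.h)


def trace_mean_cw_bias(
    trace: CheYTrace,
    hill: HillParams,
    statistic: str = "mean_of_hill",
) -> float:
    """Mean CW bias of a CheY-P trace.

    ``"mean_of_hill"``: time-average of the instantaneous
    Hill-transformed bias (the default; this is what the motors
    integrate).  ``"hill_of_mean"``: Hill map applied to the
    time-averaged concentration.
    """
    if trace.values.size == 0:
        raise ParameterError("empty trace")
    if statistic == "mean_of_hill":
        return float(np.mean(hill_cw_bias(trace.values, hill)))
    if statistic == "hill_of_mean":
        return float(hill_cw_bias(float(np.mean(trace.values)), hill))
    raise ValueError(f"unknown statistic {statistic!r}")


def accept_trace(
    trace: CheYTrace,
    hill: HillParams,
    cb_range: Tuple[float, float] = (0.13, 0.145),
    statistic: str = "mean_of_hill",
) -> bool:
    """True iff the trace's mean CW bias lies inside ``cb_range``."""
    mean_cb = trace_mean_cw_bias(trace, hill, statistic)
    return cb_range[0] <= mean_cb <= cb_range[1]


def generate_accepted_trace(
    params: FluctuationParams,
    hill: HillParams,
    duration: float,
    seed=None,
    cb_range: Tuple[float, float] = (0.13, 0.145),
    statistic: str = "mean_of_hill",
    max_attempts: int = 1000,
) -> CheYTrace:
    """Regenerate OU traces until one passes the acceptance band.

    Raises :class:`TraceAcceptanceError` (carrying the attempted mean
    biases) if ``max_attempts`` traces are all rejected.
    """
    rng = _as_rng(seed)
    attempted = []
    for _ in range(max_attempts):
        trace = simulate_chey_trace(params, duration, seed=rng)
        mean_cb = trace_mean_cw_bias(trace, hill, statistic)
        if cb_range[0] <= mean_cb <= cb_range[1]:
            return trace
        attempted.append(mean_cb)
    raise TraceAcceptanceError(
        f"no trace accepted into CB range {cb_range} after {max_attempts} attempts "
        f"(attempted means: {np.mean(attempted):.4f} ± {np.std(attempted):.4f})",
        attempted,
    )
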