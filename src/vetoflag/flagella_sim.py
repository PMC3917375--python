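"""Per-flagellum motor switching, waveform overlay and whole-cell assembly.

Each flagellar motor is a two-state (CCW=0 / CW=1) telegraph process
driven by a shared instantaneous CW-bias series cb(t):

    P(CCW→CW in dt) = cb(t)/omega * dt,
    P(CW→CCW in dt) = (1-cb(t))/omega * dt,

so the conditional CW occupancy tracks cb(t) with relaxation time
omega.  All motors on a cell see the same cb(t) (the shared CheY-P
pool) but flip with independent noise streams.

The binary motor trace is optionally converted to a 3-state filament
waveform trace (normal / semi-coiled / curly-1), and the cell's
run/tumble series follows from a run rule — by default the veto rule:
the cell runs iff every flagellum rotates CCW.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .params import ModelParams, MotorParams, ParameterError, WaveformParams
from . import chey_dynamics
from .chey_dynamics import CheYTrace

CCW, CW = 0, 1
NORMAL, SEMI_COILED, CURLY_1 = 0, 1, 2

WAVEFORM_NAMES = {NORMAL: "normal", SEMI_COILED: "semi_coiled", CURLY_1: "curly_1"}


class StabilityError(ValueError):
    """dt times the largest switching rate is too large for Euler steps."""


# ---------------------------------------------------------------------------
# motor kernel (numba-accelerated when available)


def _motor_kernel_py(cb, inv_omega_dt, u_init, us):
    n = cb.shape[0]
    states = np.empty(n, dtype=np.int8)
    state = 1 if u_init < cb[0] else 0
    for t in range(n):
        states[t] = state
        p = cb[t] * inv_omega_dt if state == 0 else (1.0 - cb[t]) * inv_omega_dt
        if us[t] < p:
            state = 1 - state
    return states


try:  # pragma: no cover - exercised implicitly
    import numba

    _motor_kernel = numba.njit(cache=True)(_motor_kernel_py)
except Exception:  # pragma: no cover
    _motor_kernel = _motor_kernel_py


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MotorTrace:
    """Binary CCW/CW rotational state series at resolution dt."""

    states: np.ndarray  # int8, 0=CCW, 1=CW
    dt: float

    @property
    def cw_fraction(self) -> float:
        return float(np.mean(self.states == CW))


@dataclass
class WaveformTrace:
    """3-state filament waveform series aligned with a MotorTrace."""

    states: np.ndarray  # int8 in {NORMAL, SEMI_COILED, CURLY_1}
    dt: float


@dataclass
class CellRecord:
    """Ground-truth per-cell simulation output at resolution dt."""

    n_flag: int
    dt: float
    motor: np.ndarray  # (n_flag, T) int8
    tumble: np.ndarray  # (T,) int8, 1 = tumble
    waveform: Optional[np.ndarray] = None  # (n_flag, T) int8
    chey_trace: Optional[CheYTrace] = None
    strain_mode: str = "constant_cb"
    seed: Optional[int] = None
    cell_id: str = ""
    cb_target: float = float("nan")

    @property
    def duration(self) -> float:
        return self.motor.shape[1] * self.dt

    @property
    def step(self) -> float:
        return self.dt


def simulate_motor(cb_series, omega: float, dt: float, seed=None) -> MotorTrace:
    """Simulate one motor driven by a CW-bias series (or a constant).

    The initial state is drawn Bernoulli(cb[0]) — stationarity at the
    initial bias.  Refuses steps where dt times the fastest rate
    exceeds 0.1 (Euler-step validity).
    """
    rng = _as_rng(seed)
    cb = np.asarray(cb_series, dtype=float)
    if cb.ndim == 0:
        raise ValueError("pass a series; use np.full(n, cb) for a constant bias")
    if np.any(cb < 0) or np.any(cb > 1):
        raise ParameterError("cb values must lie in [0, 1]")
    max_rate = max(np.max(cb), np.max(1.0 - cb)) / omega
    if dt * max_rate > 0.1:
        raise StabilityError(
            f"dt*max_rate = {dt * max_rate:.3f} > 0.1; reduce dt or increase omega"
        )
    states = _motor_kernel(cb, dt / omega, rng.random(), rng.random(cb.size))
    return MotorTrace(states=states, dt=dt)


def overlay_waveforms(
    motor: MotorTrace,
    params: WaveformParams,
    seed=None,
) -> WaveformTrace:
    """Convert a binary CCW/CW trace into a 3-state waveform trace.

    CCW intervals are *normal*.  At each CCW→CW switch the filament
    enters *semi-coiled* with probability 1 - entry_prob_curly and
    *curly-1* otherwise; a semi-coiled filament converts to curly-1 at
    rate ``lambda_rate`` within the CW interval and never reverts.
    """
    rng = _as_rng(seed)
    s = motor.states
    n = s.size
    wf = np.zeros(n, dtype=np.int8)  # NORMAL everywhere by default
    padded = np.diff(np.concatenate(([0], s.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    if starts.size:
        enter_curly = rng.random(starts.size) < params.entry_prob_curly
        # conversion waiting times for semi-coiled entries
        if params.lambda_rate > 0:
            conv_steps = rng.exponential(1.0 / params.lambda_rate, size=starts.size) / motor.dt
        else:
            conv_steps = np.full(starts.size, np.inf)
        for k in range(starts.size):
            i, j = starts[k], ends[k]
            if enter_curly[k]:
                wf[i:j] = CURLY_1
            else:
                switch = i + int(conv_steps[k]) + 1 if np.isfinite(conv_steps[k]) else j
                if switch >= j:
                    wf[i:j] = SEMI_COILED
                else:
                    wf[i:switch] = SEMI_COILED
                    wf[switch:j] = CURLY_1
    return WaveformTrace(states=wf, dt=motor.dt)


def apply_run_rule(
    waveform_traces: Sequence[np.ndarray],
    params: Optional[WaveformParams] = None,
    seed=None,
    variant: str = "veto",
) -> np.ndarray:
    """Run/tumble series (1 = tumble) from per-flagellum state traces.

    ``variant="veto"``: the cell runs iff all flagella are CCW
    (*normal*); any CW flagellum vetoes the run.  Accepts binary motor
    traces or 3-state waveform traces (any non-normal state counts CW).

    ``variant="curly_run"``: veto, except each maximal interval with
    exactly one curly-1 flagellum and all others normal is relabeled a
    run with probability ``params.curly_run_prob`` (one Bernoulli draw
    per interval) — cells with a single curly-1 filament run ~18% of
    the time.

    ``variant="x_rule"``: intervals with at least ``params.x_rule``
    normal flagella and every CW flagellum in curly-1 are runs.
    """
    mats = np.asarray(waveform_traces)
    if mats.ndim != 2:
        raise ValueError("expected a (n_flag, T) array of state traces")
    lengths = {m.size for m in mats}
    if len(lengths) != 1:
        raise ValueError("trace lengths differ")
    cw = mats != NORMAL  # for binary motor traces NORMAL==CCW==0
    tumble = np.any(cw, axis=0).astype(np.int8)

    if variant == "veto":
        return tumble

    if params is None:
        raise ValueError(f"variant {variant!r} requires WaveformParams")
    is_curly = mats == CURLY_1
    n_cw = cw.sum(axis=0)
    n_curly = is_curly.sum(axis=0)

    if variant == "curly_run":
        rng = _as_rng(seed)
        eligible = (n_cw == 1) & (n_curly == 1)
        out = tumble.copy()
        padded = np.diff(np.concatenate(([0], eligible.astype(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for i, j in zip(starts, ends):
            if rng.random() < params.curly_run_prob:
                out[i:j] = 0
        return out

    if variant == "x_rule":
        if params.x_rule is None:
            raise ValueError("x_rule variant requires params.x_rule")
        n_normal = mats.shape[0] - n_cw
        run_extra = (n_normal >= params.x_rule) & (n_cw == n_curly)
        out = tumble.copy()
        out[run_extra] = 0
        return out

    raise ValueError(f"unknown run-rule variant {variant!r}")


def simulate_cell(
    model: ModelParams,
    n_flag: int,
    duration: float,
    strain_mode: str = "wildtype_fluctuating",
    seed=None,
    cb_constant: Optional[float] = None,
    y_mean: Optional[float] = None,
    cb_range: Optional[tuple] = (0.13, 0.145),
    accept_statistic: str = "mean_of_hill",
    max_attempts: int = 1000,
    with_waveforms: bool = True,
    run_rule_variant: str = "veto",
) -> CellRecord:
    """Simulate one cell: shared CB(t) drive, N motors, run/tumble labels.

    ``strain_mode="wildtype_fluctuating"`` draws an OU CheY-P trace
    (mean ``y_mean``, default the model's), maps it through the Hill
    function, and rejects traces whose mean CW bias misses ``cb_range``
    (pass None to skip the filter).  ``strain_mode="constant_cb"``
    drives all motors with the fixed bias ``cb_constant`` (default the
    model's mean CB) — the constitutively-active-CheY control, for
    which flagella switch independently.

    Motors use independent child streams of ``seed`` so that adding a
    flagellum never perturbs the trajectories of the others.
    """
    if n_flag < 1:
        raise ParameterError("n_flag must be >= 1")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(n_flag + 2)
    drive_rng = np.random.default_rng(children[0])
    rule_rng = np.random.default_rng(children[1])

    n_steps = int(round(duration / model.dt))
    chey: Optional[CheYTrace] = None
    if strain_mode == "wildtype_fluctuating":
        fluct = model.fluctuation
        if y_mean is not None:
            from dataclasses import replace

            fluct = replace(fluct, y_mean=y_mean)
        if cb_range is None:
            chey = chey_dynamics.simulate_chey_trace(fluct, duration, seed=drive_rng)
        else:
            chey = chey_dynamics.generate_accepted_trace(
                fluct, model.hill, duration, seed=drive_rng,
                cb_range=cb_range, statistic=accept_statistic,
                max_attempts=max_attempts,
            )
        cb_series = chey_dynamics.hill_cw_bias(chey.values, model.hill)
        cb_target = float(np.mean(cb_series))
    elif strain_mode == "constant_cb":
        cb_val = model.cb if cb_constant is None else float(cb_constant)
        if not (0 <= cb_val <= 1):
            raise ParameterError("cb_constant must lie in [0, 1]")
        cb_series = np.full(n_steps, cb_val)
        cb_target = cb_val
    else:
        raise ValueError(f"unknown strain_mode {strain_mode!r}")

    motors = np.empty((n_flag, cb_series.size), dtype=np.int8)
    waveforms = np.empty_like(motors) if with_waveforms else None
    for i in range(n_flag):
        flag_rng = np.random.default_rng(children[i + 2])
        trace = simulate_motor(cb_series, model.motor.omega, model.dt, seed=flag_rng)
        motors[i] = trace.states
        if with_waveforms:
            waveforms[i] = overlay_waveforms(trace, model.waveform, seed=flag_rng).states

    rule_input = waveforms if (with_waveforms and run_rule_variant != "veto") else motors
    tumble = apply_run_rule(rule_input, model.waveform, seed=rule_rng, variant=run_rule_variant)

    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return CellRecord(
        n_flag=n_flag, dt=model.dt, motor=motors, tumble=tumble,
        waveform=waveforms, chey_trace=chey, strain_mode=strain_mode,
        seed=seed_val, cb_target=cb_target,
    )
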