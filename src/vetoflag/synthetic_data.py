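"""Synthetic trapped-cell datasets.

Generates cohorts with the population structure and observation
process the analyses assume: per-cell flagellar numbers (zero-truncated
Poisson), per-cell CW-bias heterogeneity (truncated normal,
0.11 ± 0.07), trace durations of 8-40 s (the photobleaching window of
the fluorescence assay), and per-flagellum state calls in 100-ms
observation windows (majority vote, ties carrying the previous call).

Both the windowed observations and the underlying ground-truth records
are returned, so estimator consistency can be checked directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .params import ModelParams, ParameterError
from . import chey_dynamics, flagella_sim
from .flagella_sim import CellRecord


@dataclass
class ObservedCell:
    """Windowed (image-analysis style) state calls for one cell."""

    cell_id: str
    n_flag: int
    motor: np.ndarray  # (n_flag, n_windows) int8 CCW/CW calls
    tumble: np.ndarray  # (n_windows,) int8 run/tumble calls
    waveform: Optional[np.ndarray]  # (n_flag, n_windows) int8 or None
    window: float  # s
    duration: float  # s
    strain: str = ""

    @property
    def step(self) -> float:
        return self.window

    @property
    def strain_mode(self) -> str:
        return self.strain


@dataclass
class PopulationConfig:
    """Cohort-level generator settings.

    ``cb_population`` is the (mean, SD) of the per-cell CW-bias targets,
    drawn from a normal truncated to ``cb_truncation`` — matching the
    0.11 ± 0.07 spread of trapped-cell cohorts, restricted to the
    0-0.25 range the analyses use.  In fluctuating mode the per-cell
    mean CheY-P is set so the Hill map hits the drawn target
    (``heterogeneity="per_cell_y"``), and candidate CheY-P traces are
    accepted within ±``accept_half_width`` of the target; the
    ``"population"`` alternative keeps one global mean CheY-P and the
    fixed acceptance band ``population_band``.
    """

    n_cells: int = 100
    strain_mode: str = "wildtype_fluctuating"
    nflag_mean: float = 3.4  # zero-truncated Poisson mean
    nflag_values: Optional[Sequence[int]] = None  # explicit per-cell override
    cb_population: Tuple[float, float] = (0.11, 0.07)
    cb_truncation: Tuple[float, float] = (0.0, 0.25)
    duration_range: Tuple[float, float] = (8.0, 40.0)
    window: float = 0.1
    heterogeneity: str = "per_cell_y"  # or "population"
    accept_half_width: float = 0.0075
    population_band: Tuple[float, float] = (0.13, 0.145)
    accept_statistic: str = "mean_of_hill"
    max_attempts: int = 1000
    misclassification: float = 0.0  # per-window observation noise
    with_waveforms: bool = True
    run_rule_variant: str = "veto"
    model: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.duration_range[0] <= 0:
            raise ParameterError("durations must be positive")
        if self.window < self.model.dt:
            raise ParameterError("window must be >= dt")
        if self.strain_mode not in ("wildtype_fluctuating", "constant_cb"):
            raise ParameterError(f"unknown strain_mode {self.strain_mode!r}")
        if self.heterogeneity not in ("per_cell_y", "population"):
            raise ParameterError(f"unknown heterogeneity mode {self.heterogeneity!r}")
        if not (0 <= self.misclassification < 1):
            raise ParameterError("misclassification must lie in [0, 1)")


def _zero_truncated_poisson(mean: float, rng: np.random.Generator) -> int:
    if mean <= 0:
        raise ParameterError("nflag_mean must be > 0")
    while True:
        k = rng.poisson(mean)
        if k >= 1:
            return int(k)


def _truncated_normal(
    mean: float, sd: float, bounds: Tuple[float, float], rng: np.random.Generator
) -> float:
    lo, hi = bounds
    for _ in range(100000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    raise ParameterError(f"truncated normal ({mean}, {sd}) never hit ({lo}, {hi}]")


def _majority_calls(series: np.ndarray, window_steps: int, n_states: int) -> np.ndarray:
    """Majority state per window; exact ties carry the previous call."""
    n_windows = series.size // window_steps
    clipped = series[: n_windows * window_steps].reshape(n_windows, window_steps)
    counts = np.stack([(clipped == s).sum(axis=1) for s in range(n_states)], axis=1)
    calls = np.argmax(counts, axis=1).astype(np.int8)
    top = counts.max(axis=1)
    n_top = (counts == top[:, None]).sum(axis=1)
    prev = int(series[0])
    for w in range(n_windows):
        if n_top[w] > 1:
            calls[w] = prev
        prev = calls[w]
    return calls


def discretize_observations(
    cell: CellRecord,
    window: float = 0.1,
    cell_id: str = "",
    misclassification: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> ObservedCell:
    """Windowed state calls emulating manual image analysis.

    Each window's call is the majority state within the window — motor,
    waveform and run/tumble series independently.  An optional
    per-window misclassification probability flips calls uniformly to
    another state (an estimator stress test, not an observed feature).
    """
    if window < cell.dt:
        raise ParameterError("window must be >= dt")
    window_steps = int(round(window / cell.dt))
    motor = np.vstack([
        _majority_calls(cell.motor[f], window_steps, 2) for f in range(cell.n_flag)
    ])
    tumble = _majority_calls(cell.tumble, window_steps, 2)
    waveform = None
    if cell.waveform is not None:
        waveform = np.vstack([
            _majority_calls(cell.waveform[f], window_steps, 3)
            for f in range(cell.n_flag)
        ])
    if misclassification > 0:
        if rng is None:
            rng = np.random.default_rng()
        flip = rng.random(motor.shape) < misclassification
        motor = np.where(flip, 1 - motor, motor).astype(np.int8)
        flip_t = rng.random(tumble.shape) < misclassification
        tumble = np.where(flip_t, 1 - tumble, tumble).astype(np.int8)
    return ObservedCell(
        cell_id=cell_id or cell.cell_id,
        n_flag=cell.n_flag,
        motor=motor,
        tumble=tumble,
        waveform=waveform,
        window=window,
        duration=motor.shape[1] * window,
        strain=cell.strain_mode,
    )


def sample_population(
    config: PopulationConfig, seed=None
) -> Tuple[List[ObservedCell], List[CellRecord]]:
    """Draw a cohort of cells and their windowed observations.

    Returns (observations, ground_truth) in matching order; both are
    reproducible bitwise from (config, seed).
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    cell_seeds = ss.spawn(config.n_cells)

    observed: List[ObservedCell] = []
    truth: List[CellRecord] = []
    for i in range(config.n_cells):
        if config.nflag_values is not None:
            n_flag = int(config.nflag_values[i % len(config.nflag_values)])
        else:
            n_flag = _zero_truncated_poisson(config.nflag_mean, draw_rng)
        duration = draw_rng.uniform(*config.duration_range)
        cb_target = _truncated_normal(
            *config.cb_population, config.cb_truncation, draw_rng
        )

        kwargs = dict(
            model=config.model,
            n_flag=n_flag,
            duration=duration,
            seed=cell_seeds[i],
            with_waveforms=config.with_waveforms,
            run_rule_variant=config.run_rule_variant,
            accept_statistic=config.accept_statistic,
            max_attempts=config.max_attempts,
        )
        if config.strain_mode == "constant_cb":
            record = flagella_sim.simulate_cell(
                strain_mode="constant_cb", cb_constant=cb_target, **kwargs
            )
        elif config.heterogeneity == "per_cell_y":
            y_mean = chey_dynamics.hill_inverse(cb_target, config.model.hill)
            band = (
                cb_target - config.accept_half_width,
                cb_target + config.accept_half_width,
            )
            record = flagella_sim.simulate_cell(
                strain_mode="wildtype_fluctuating", y_mean=y_mean,
                cb_range=band, **kwargs
            )
        else:  # population-level acceptance at the global mean CheY-P
            record = flagella_sim.simulate_cell(
                strain_mode="wildtype_fluctuating",
                cb_range=config.population_band, **kwargs
            )
        record.cell_id = f"cell{i:04d}"
        record.cb_target = cb_target
        obs_rng = (
            np.random.default_rng(cell_seeds[i].spawn(1)[0])
            if config.misclassification > 0 else None
        )
        obs = discretize_observations(
            record, window=config.window, cell_id=record.cell_id,
            misclassification=config.misclassification, rng=obs_rng,
        )
        observed.append(obs)
        truth.append(record)
    return observed, truth
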