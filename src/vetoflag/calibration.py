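"""Calibration of the CheY-P fluctuation parameters (σ², τ).

The two free parameters of the fluctuating-CheY-P model are fitted by
a grid scan: at each (σ², τ) a synthetic population is simulated with
common random numbers, four summary statistics are computed —

  1. mean maximum number of CW flagella per tumble, vs n_flag,
  2. the pair cross-correlation curve,
  3. the effective flagellar number N_eff, vs n_flag,
  4. the veto-model deviation η, vs n_flag,

— and each is scored against a target table by a reduced χ²
(dof = #points − 2 for the two fitted parameters).  The global
objective is the sum of the component reduced χ² values; the reported
optimum is its argmin on the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import model_core, trace_analysis
from .model_core import ChiSqResult
from .params import ModelParams, ParameterError
from .synthetic_data import PopulationConfig, sample_population

logger = logging.getLogger(__name__)

STATISTICS = ("mean_max_cw", "cross_correlation", "n_eff", "eta")

DEFAULT_SIGMA2_GRID = tuple(np.arange(0.25, 2.01, 0.25))
DEFAULT_TAU_GRID = tuple(np.arange(1.0, 10.01, 1.0))


@dataclass
class SimulationPlan:
    """How much to simulate per grid point."""

    cells_per_group: int = 25
    n_flag_groups: Tuple[int, ...] = (1, 2, 3, 4, 5)
    duration: Tuple[float, float] = (8.0, 40.0)
    max_lag: float = 2.0  # lags well past tau are what discriminate timescales
    lag_points: int = 6  # cross-correlation lags compared (>= 0 only)
    base_config: PopulationConfig = field(default_factory=PopulationConfig)


@dataclass
class CalibrationGrid:
    """χ² surface over the (σ², τ) grid and its minimum."""

    sigma2_values: np.ndarray
    tau_values: np.ndarray
    chi2_surface: np.ndarray  # shape (len(sigma2), len(tau)); NaN = invalid point
    best: Tuple[float, float]
    replicates: int
    seed: Optional[int]
    components: Dict[Tuple[float, float], ChiSqResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s2 in enumerate(self.sigma2_values):
            for j, tau in enumerate(self.tau_values):
                rows.append({"sigma2": s2, "tau": tau, "chi2": self.chi2_surface[i, j]})
        return pd.DataFrame(rows)


def summarize_population(
    observed: Sequence,
    plan: SimulationPlan,
) -> Dict[str, pd.DataFrame]:
    """The four calibration summary tables for one simulated cohort."""
    summaries = [trace_analysis.summarize_cell(c) for c in observed]
    usable = [s for s in summaries if s.eta_defined]

    eta_df = trace_analysis.group_eta(usable)

    n_eff_rows = []
    for n_flag in sorted({s.n_flag for s in usable}):
        group = [s for s in usable if s.n_flag == n_flag]
        if len(group) >= 2:
            fit = model_core.fit_n_eff(group)
            # SE from the spread of the per-cell closed-form estimates
            per_cell = np.array([
                np.log1p(-s.tb) / np.log1p(-s.cb) for s in group
            ])
            sem = float(per_cell.std(ddof=1) / np.sqrt(len(group)))
            n_eff_rows.append({"n_flag": n_flag, "value": fit.n_eff,
                               "sem": max(sem, 0.05)})
    n_eff_df = pd.DataFrame(n_eff_rows)

    # per-cell averaging: events within a cell are correlated, so the
    # event-level SEM would understate the cohort-level uncertainty
    max_cw_df = trace_analysis.mean_max_cw(observed, per_cell=True)
    xc_df = trace_analysis.population_cross_correlation(
        observed, max_lag=plan.max_lag
    )
    if not xc_df.empty:
        pos = xc_df[xc_df.lag_s >= 0].reset_index(drop=True)
        idx = np.linspace(0, len(pos) - 1, min(plan.lag_points, len(pos))).astype(int)
        xc_df = pos.iloc[idx]
    return {
        "mean_max_cw": max_cw_df,
        "cross_correlation": xc_df,
        "n_eff": n_eff_df,
        "eta": eta_df,
    }


def make_targets(tables: Dict[str, pd.DataFrame], sems: Optional[Dict[str, float]] = None) -> pd.DataFrame:
    """Long-format target table (statistic, x, value, sem) from summaries."""
    rows = []
    for stat, df in tables.items():
        if df.empty:
            continue
        if stat == "mean_max_cw":
            for _, r in df.iterrows():
                rows.append((stat, r.n_flag, r.mean_max_cw, r["sem"]))
        elif stat == "cross_correlation":
            for _, r in df.iterrows():
                rows.append((stat, r.lag_s, r.value, r["sem"]))
        elif stat == "n_eff":
            for _, r in df.iterrows():
                sem = r["sem"] if "sem" in df.columns else (sems or {}).get(stat, 0.15)
                rows.append((stat, r.n_flag, r.value, sem))
        elif stat == "eta":
            for _, r in df.iterrows():
                rows.append((stat, r.n_flag, r.eta_mean, r["sem"]))
    out = pd.DataFrame(rows, columns=["statistic", "x", "value", "sem"])
    floor = (sems or {}).get("floor", 0.02)
    out["sem"] = out["sem"].fillna(floor).clip(lower=floor)
    return out


def _component_chi2(
    sim_tables: Dict[str, pd.DataFrame], targets: pd.DataFrame
) -> ChiSqResult:
    """Per-statistic reduced χ², scored against the combined uncertainty.

    Both the targets and the grid-point simulation are Monte-Carlo
    estimates, so residuals are normalized by
    sqrt(sem_target² + sem_sim²).
    """
    sim_long = make_targets(sim_tables)
    comps = []
    for stat in STATISTICS:
        tgt = targets[targets.statistic == stat].copy()
        sim = sim_long[sim_long.statistic == stat].copy()
        if tgt.empty or sim.empty:
            continue
        tgt["key"] = np.round(tgt.x.astype(float), 6)
        sim["key"] = np.round(sim.x.astype(float), 6)
        merged = tgt.merge(sim, on="key", suffixes=("_t", "_s"))
        merged = merged[np.isfinite(merged.value_s)]
        if len(merged) >= 3:
            combined_sem = np.sqrt(merged.sem_t ** 2 + merged.sem_s ** 2)
            comps.append(
                model_core.reduced_chi_square(
                    merged.value_s, merged.value_t, combined_sem, n_params=2
                )
            )
    if not comps:
        raise ParameterError("no overlapping statistics between simulation and targets")
    return model_core.global_reduced_chi_square(comps)


def scan_fluctuation_params(
    targets: pd.DataFrame,
    sigma2_values: Sequence[float] = DEFAULT_SIGMA2_GRID,
    tau_values: Sequence[float] = DEFAULT_TAU_GRID,
    plan: Optional[SimulationPlan] = None,
    seed: Optional[int] = None,
) -> CalibrationGrid:
    """Grid scan of (σ², τ) minimizing the global reduced χ².

    Simulations at different grid points reuse the same seed (common
    random numbers), which smooths the χ² surface.  Grid points whose
    simulation fails are marked invalid (NaN) and excluded from the
    argmin.
    """
    sigma2_values = np.asarray(list(sigma2_values), dtype=float)
    tau_values = np.asarray(list(tau_values), dtype=float)
    if sigma2_values.size == 0 or tau_values.size == 0:
        raise ParameterError("empty calibration grid")
    plan = plan or SimulationPlan()

    surface = np.full((sigma2_values.size, tau_values.size), np.nan)
    components: Dict[Tuple[float, float], ChiSqResult] = {}
    for i, s2 in enumerate(sigma2_values):
        for j, tau in enumerate(tau_values):
            cfg = plan.base_config
            fluct = replace(cfg.model.fluctuation, sigma2=float(s2), tau=float(tau))
            model = replace(cfg.model, fluctuation=fluct)
            cfg_ij = replace(
                cfg,
                model=model,
                n_cells=plan.cells_per_group * len(plan.n_flag_groups),
                nflag_values=tuple(np.repeat(plan.n_flag_groups, plan.cells_per_group)),
                duration_range=plan.duration,
            )
            try:
                observed, _ = sample_population(cfg_ij, seed=seed)
                sim_tables = summarize_population(observed, plan)
                res = _component_chi2(sim_tables, targets)
            except Exception as exc:  # invalid point: exclude from argmin
                logger.warning("grid point (σ²=%g, τ=%g) failed: %s", s2, tau, exc)
                continue
            surface[i, j] = res.chi2_reduced
            components[(float(s2), float(tau))] = res

    if np.all(np.isnan(surface)):
        raise ParameterError("every grid point failed")
    flat = np.nanargmin(surface)
    bi, bj = np.unravel_index(flat, surface.shape)
    return CalibrationGrid(
        sigma2_values=sigma2_values,
        tau_values=tau_values,
        chi2_surface=surface,
        best=(float(sigma2_values[bi]), float(tau_values[bj])),
        replicates=plan.cells_per_group,
        seed=seed,
        components=components,
    )
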