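"""Veto-model algebra and population-level estimators.

The veto model maps a cell's per-flagellum clockwise bias CB and its
flagellar number N to its tumble bias TB.  A run requires every
flagellum to rotate CCW, so for independently switching flagella

    TB = 1 - (1 - CB)**N.

Deviations from this identity are quantified per cell by

    eta = log(1 - TB) / log(1 - CB) - N,

which is zero for independent flagella and negative when flagella
switch in a correlated manner (the cell tumbles less than N
independent flagella would make it).  The generalized model replaces N
with a fitted effective flagellar number N_eff:

    1 - TB = (1 - CB)**N_eff.

This module implements the algebra, the per-group N_eff least-squares
fit, the power-law summary of N_eff versus N, and the reduced chi².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

N_EFF_BOUNDS = (1e-9, 20.0)


class DomainError(ValueError):
    """Input outside the mathematical domain of an estimator."""


class UndefinedStatisticError(ValueError):
    """eta (or a fit) is undefined for the given biases."""


@dataclass
class CellSummary:
    """Per-cell swimming summary: flagellar number, tumble and CW bias."""

    n_flag: int
    tb: float
    cb: float
    eta: Optional[float] = None
    cell_id: str = ""
    strain: str = ""
    duration_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_flag < 1:
            raise DomainError(f"n_flag must be >= 1, got {self.n_flag}")
        if not (0 <= self.tb <= 1):
            raise DomainError(f"tb must lie in [0, 1], got {self.tb}")
        if not (0 <= self.cb <= 1):
            raise DomainError(f"cb must lie in [0, 1], got {self.cb}")

    @property
    def eta_defined(self) -> bool:
        return 0.0 < self.cb < 1.0 and self.tb < 1.0


@dataclass
class GroupFit:
    """Effective flagellar number fitted to one n_flag group."""

    n_flag: int
    n_eff: float
    r_squared: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_eff <= 0:
            raise DomainError("n_eff must be > 0")
        if self.n_cells < 1:
            raise DomainError("n_cells must be >= 1")
        if self.r_squared > 1 + 1e-12:
            raise DomainError("r_squared cannot exceed 1")


@dataclass
class PowerLawFit:
    """n_eff ≈ a * n_flag**b across groups."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise DomainError("prefactor a must be > 0")

    def __call__(self, n_flag):
        return self.a * np.asarray(n_flag, dtype=float) ** self.b


@dataclass
class ChiSqResult:
    """Reduced chi-square, possibly summed over component datasets."""

    chi2_reduced: float
    dof: int
    per_dataset: tuple = ()

    def __post_init__(self) -> None:
        if self.chi2_reduced < 0:
            raise DomainError("chi2_reduced must be >= 0")
        if self.dof < 1:
            raise DomainError("dof must be >= 1")


# ---------------------------------------------------------------------------
# algebra


def veto_tumble_bias(cb, n):
    """Tumble bias of a cell with ``n`` independent flagella of CW bias ``cb``.

    ``n`` may be real-valued (effective flagellar numbers trace the same
    family of curves).  Vectorized over both arguments.
    """
    cb_arr = np.asarray(cb, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(cb_arr < 0) or np.any(cb_arr > 1):
        raise DomainError("cb must lie in [0, 1]")
    if np.any(n_arr < 0):
        raise DomainError("n must be >= 0")
    out = 1.0 - (1.0 - cb_arr) ** n_arr
    if np.isscalar(cb) and np.isscalar(n):
        return float(out)
    return out


def deviation_eta(tb: float, cb: float, n_flag: float) -> float:
    """Deviation of a cell from the veto prediction.

    Zero when TB satisfies the veto identity; negative when the cell
    tumbles less than ``n_flag`` independent flagella would imply.
    Undefined (raises) for cb in {0, 1} or tb = 1.
    """
    if not (0 <= tb <= 1) or not (0 <= cb <= 1):
        raise DomainError("tb and cb must lie in [0, 1]")
    if cb <= 0.0 or cb >= 1.0 or tb >= 1.0:
        raise UndefinedStatisticError(
            f"eta undefined for tb={tb}, cb={cb} (needs 0 < cb < 1 and tb < 1)"
        )
    return float(np.log1p(-tb) / np.log1p(-cb) - n_flag)


def eta_or_none(tb: float, cb: float, n_flag: float) -> Optional[float]:
    """deviation_eta, returning None instead of raising when undefined."""
    try:
        return deviation_eta(tb, cb, n_flag)
    except UndefinedStatisticError:
        return None


# ---------------------------------------------------------------------------
# fitting


def _usable_arrays(cells: Sequence[CellSummary]):
    """tb/cb arrays for cells on which the generalized curve is fittable."""
    kept = [c for c in cells if c.eta_defined]
    dropped = len(cells) - len(kept)
    if dropped:
        warnings.warn(
            f"excluded {dropped} cell(s) with degenerate biases (cb in {{0,1}} or tb=1)",
            stacklevel=3,
        )
    tb = np.array([c.tb for c in kept], dtype=float)
    cb = np.array([c.cb for c in kept], dtype=float)
    return tb, cb, len(kept)


def _r_squared(tb: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((tb - predicted) ** 2))
    ss_tot = float(np.sum((tb - tb.mean()) ** 2))
    if ss_tot == 0.0:
        raise DomainError("zero total variance in tb; R² undefined")
    return 1.0 - ss_res / ss_tot


def fit_n_eff(
    cells: Sequence[CellSummary],
    space: str = "tb",
) -> GroupFit:
    """Least-squares effective flagellar number for one n_flag group.

    Minimizes sum_i (tb_i - [1 - (1-cb_i)**N_eff])² over N_eff in
    (0, 20] (``space="tb"``), or ordinary least squares of
    log(1-tb) = N_eff·log(1-cb) through the origin (``space="log"``).
    A single cell returns the closed form log(1-tb)/log(1-cb).
    """
    if len(cells) == 0:
        raise DomainError("fit_n_eff requires at least one cell")
    n_flags = {c.n_flag for c in cells}
    if len(n_flags) > 1:
        raise DomainError(f"cells span multiple n_flag groups: {sorted(n_flags)}")
    n_flag = n_flags.pop()

    tb, cb, n_kept = _usable_arrays(cells)
    if n_kept == 0:
        raise DomainError("no cells with usable (non-degenerate) biases remain")

    log_ratio = np.log1p(-tb) / np.log1p(-cb)  # per-cell closed-form N_eff

    if n_kept == 1:
        n_eff = float(log_ratio[0])
        return GroupFit(n_flag=n_flag, n_eff=max(n_eff, N_EFF_BOUNDS[0]), r_squared=1.0, n_cells=1)

    if space == "log":
        x = np.log1p(-cb)
        y = np.log1p(-tb)
        n_eff = float(np.dot(x, y) / np.dot(x, x))
    elif space == "tb":
        def sse(n):
            return float(np.sum((tb - (1.0 - (1.0 - cb) ** n)) ** 2))

        res = minimize_scalar(sse, bounds=N_EFF_BOUNDS, method="bounded",
                              options={"xatol": 1e-10})
        n_eff = float(res.x)
        # the objective is unimodal on observed ranges; the per-cell median
        # guards against a boundary solution on degenerate inputs
        median_start = float(np.clip(np.median(log_ratio), *N_EFF_BOUNDS))
        if sse(median_start) < sse(n_eff):
            n_eff = median_start
    else:
        raise ValueError(f"unknown fit space {space!r}")

    n_eff = float(np.clip(n_eff, *N_EFF_BOUNDS))
    predicted = 1.0 - (1.0 - cb) ** n_eff
    try:
        r2 = _r_squared(tb, predicted)
    except DomainError:
        r2 = 1.0 if np.allclose(tb, predicted) else float("-inf")
    return GroupFit(n_flag=n_flag, n_eff=n_eff, r_squared=r2, n_cells=n_kept)


def curve_r_squared(cells: Sequence[CellSummary], n_curve: float) -> float:
    """R² of the fixed curve tb = 1-(1-cb)**n_curve against the cells.

    Used to score the naive veto prediction (n_curve = n_flag) without
    refitting; may be negative when the fixed curve is a poor summary.
    """
    if len(cells) < 2:
        raise DomainError("curve_r_squared requires at least two cells")
    tb, cb, n_kept = _usable_arrays(cells)
    if n_kept < 2:
        raise DomainError("fewer than two usable cells")
    predicted = 1.0 - (1.0 - cb) ** float(n_curve)
    return _r_squared(tb, predicted)


def fit_power_law(group_fits: Sequence[GroupFit]) -> PowerLawFit:
    """Unweighted log-log least squares of n_eff against n_flag."""
    if len(group_fits) < 2:
        raise DomainError("fit_power_law requires at least two groups")
    n_flag = np.array([g.n_flag for g in group_fits], dtype=float)
    n_eff = np.array([g.n_eff for g in group_fits], dtype=float)
    if len(np.unique(n_flag)) < 2:
        raise DomainError("groups must have distinct n_flag")
    if np.any(n_eff <= 0):
        raise DomainError("n_eff must be positive for the log-log fit")
    b, log_a = np.polyfit(np.log(n_flag), np.log(n_eff), 1)
    return PowerLawFit(a=float(np.exp(log_a)), b=float(b))


# ---------------------------------------------------------------------------
# chi-square


def reduced_chi_square(
    sim: Iterable[float],
    obs: Iterable[float],
    sem: Iterable[float],
    n_params: int = 0,
) -> ChiSqResult:
    """Reduced chi²: sum(((sim-obs)/sem)²) / (len - n_params)."""
    sim_a = np.asarray(list(sim), dtype=float)
    obs_a = np.asarray(list(obs), dtype=float)
    sem_a = np.asarray(list(sem), dtype=float)
    if not (sim_a.shape == obs_a.shape == sem_a.shape):
        raise DomainError("sim, obs and sem must have equal length")
    if np.any(sem_a <= 0):
        raise DomainError("all SEMs must be > 0")
    dof = sim_a.size - n_params
    if dof < 1:
        raise DomainError(f"dof = {sim_a.size} - {n_params} < 1")
    chi2 = float(np.sum(((sim_a - obs_a) / sem_a) ** 2)) / dof
    return ChiSqResult(chi2_reduced=chi2, dof=dof)


def global_reduced_chi_square(components: Sequence[ChiSqResult]) -> ChiSqResult:
    """Global objective: the sum of component reduced chi² values."""
    if len(components) == 0:
        raise DomainError("need at least one component")
    total = float(sum(c.chi2_reduced for c in components))
    dof = int(sum(c.dof for c in components))
    return ChiSqResult(
        chi2_reduced=total, dof=dof,
        per_dataset=tuple(c.chi2_reduced for c in components),
    )
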