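"""Statistics computed from per-cell state traces.

Works on both ground-truth records (1-ms resolution) and windowed
observations (100-ms state calls): any object with attributes
``n_flag``, ``motor`` (an (n_flag, T) array of 0=CCW/1=CW calls),
``tumble`` (a (T,) array of 0=run/1=tumble calls) and ``step`` (the
sampling interval in seconds) is accepted.  ``waveform`` is required
only by the waveform-rate estimators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import model_core
from .model_core import CellSummary
from .flagella_sim import CCW, CW, NORMAL, SEMI_COILED, CURLY_1

logger = logging.getLogger(__name__)


class EmptyTraceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# per-cell biases


def cell_cw_bias(cell) -> float:
    """Mean CW bias: per-flagellum CW time-fraction, averaged over flagella."""
    motor = np.asarray(cell.motor)
    if motor.size == 0:
        raise EmptyTraceError("cell has no motor observations")
    return float(np.mean(motor == CW, axis=1).mean())


def cell_tumble_bias(cell) -> float:
    """Fraction of time the cell spends tumbling."""
    tumble = np.asarray(cell.tumble)
    if tumble.size == 0:
        raise EmptyTraceError("cell has no run/tumble observations")
    return float(np.mean(tumble == 1))


def summarize_cell(cell, cell_id: str = "", strain: str = "") -> CellSummary:
    """CellSummary (tb, cb, eta) for one record or observation."""
    tb = cell_tumble_bias(cell)
    cb = cell_cw_bias(cell)
    eta = model_core.eta_or_none(tb, cb, cell.n_flag)
    duration = np.asarray(cell.tumble).size * cell.step
    return CellSummary(
        n_flag=cell.n_flag, tb=tb, cb=cb, eta=eta,
        cell_id=cell_id or getattr(cell, "cell_id", ""),
        strain=strain or getattr(cell, "strain_mode", ""),
        duration_s=duration,
    )


# ---------------------------------------------------------------------------
# tumble events


@dataclass
class TumbleEvent:
    """One maximal contiguous tumble interval, [start, end) in seconds."""

    start: float
    end: float
    max_cw: int
    complete: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


def tumble_events(cell) -> List[TumbleEvent]:
    """Maximal tumble intervals with the peak simultaneous CW count.

    Events touching either trace boundary are flagged incomplete and
    excluded from max-CW statistics downstream (their true extent is
    censored).
    """
    tumble = np.asarray(cell.tumble).astype(np.int8)
    motor = np.asarray(cell.motor)
    n = tumble.size
    padded = np.diff(np.concatenate(([0], tumble, [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    n_cw = (motor == CW).sum(axis=0)
    events = []
    for i, j in zip(starts, ends):
        events.append(
            TumbleEvent(
                start=i * cell.step,
                end=j * cell.step,
                max_cw=int(n_cw[i:j].max()) if j > i else 0,
                complete=(i > 0 and j < n),
            )
        )
    return events


def mean_max_cw(
    cells: Sequence,
    include_incomplete: bool = False,
    per_cell: bool = False,
) -> pd.DataFrame:
    """Mean of the maximum number of CW flagella during a tumble, by n_flag.

    Default averages over complete events (SEM over events); the
    ``per_cell`` variant first averages within each cell, then over
    cells.
    """
    rows = []
    for cell in cells:
        vals = [
            e.max_cw for e in tumble_events(cell)
            if include_incomplete or e.complete
        ]
        for v in vals:
            rows.append({"n_flag": cell.n_flag, "max_cw": v, "cell": id(cell)})
    if not rows:
        return pd.DataFrame(columns=["n_flag", "mean_max_cw", "sem", "n_events"])
    df = pd.DataFrame(rows)
    if per_cell:
        df = df.groupby(["n_flag", "cell"], as_index=False)["max_cw"].mean()
    grouped = df.groupby("n_flag")["max_cw"]
    out = grouped.agg(mean_max_cw="mean", sem="sem", n_events="count").reset_index()
    return out


# ---------------------------------------------------------------------------
# cross-correlation


@dataclass
class CrossCorrelation:
    """Pair-averaged cross-correlation of binary CW indicators."""

    lags: np.ndarray  # seconds, symmetric around 0
    values: np.ndarray
    n_pairs: int


def _pair_xcorr(a: np.ndarray, b: np.ndarray, max_lag_steps: int) -> Optional[np.ndarray]:
    """Pearson-normalized, overlap-normalized cross-correlation of two
    mean-subtracted binary series for lags -max_lag..+max_lag; positive
    lag means the second series lags (is delayed relative to) the first."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return None
    da, db = a - a.mean(), b - b.mean()
    n = a.size
    out = np.empty(2 * max_lag_steps + 1)
    for idx, lag in enumerate(range(-max_lag_steps, max_lag_steps + 1)):
        if lag >= 0:
            x, y = da[: n - lag], db[lag:]
        else:
            x, y = da[-lag:], db[: n + lag]
        out[idx] = np.mean(x * y) / (sa * sb)
    return out


def pair_cross_correlation(cell, max_lag: float = 3.0) -> CrossCorrelation:
    """Cross-correlation between CW indicators of flagella pairs on a cell.

    Mean-subtracted per flagellum, Pearson-normalized per pair,
    averaged over all unordered pairs.  Zero-variance flagella
    (never/always CW in the trace) are skipped with a warning.
    """
    if cell.n_flag < 2:
        raise ValueError("cross-correlation requires n_flag >= 2")
    motor = np.asarray(cell.motor, dtype=float)
    max_lag_steps = int(round(max_lag / cell.step))
    max_lag_steps = min(max_lag_steps, motor.shape[1] - 1)
    acc = np.zeros(2 * max_lag_steps + 1)
    n_pairs = 0
    for i in range(cell.n_flag):
        for j in range(i + 1, cell.n_flag):
            xc = _pair_xcorr(motor[i], motor[j], max_lag_steps)
            if xc is None:
                warnings.warn(
                    f"skipping zero-variance flagellum pair ({i},{j})", stacklevel=2
                )
                continue
            acc += xc
            n_pairs += 1
    lags = np.arange(-max_lag_steps, max_lag_steps + 1) * cell.step
    values = acc / n_pairs if n_pairs else np.full_like(acc, np.nan)
    return CrossCorrelation(lags=lags, values=values, n_pairs=n_pairs)


def population_cross_correlation(
    cells: Sequence, max_lag: float = 3.0
) -> pd.DataFrame:
    """Cell-averaged cross-correlation curve with SEM over cells."""
    curves = []
    lags = None
    for cell in cells:
        if cell.n_flag < 2:
            continue
        xc = pair_cross_correlation(cell, max_lag=max_lag)
        if xc.n_pairs == 0:
            continue
        if lags is None or xc.lags.size < lags.size:
            lags = xc.lags
        curves.append(xc)
    if not curves:
        return pd.DataFrame(columns=["lag_s", "value", "sem"])
    m = min(c.values.size for c in curves)
    # align on the common (smallest) lag grid, trimming symmetric edges
    trimmed = []
    for c in curves:
        k = (c.values.size - m) // 2
        trimmed.append(c.values[k: k + m])
    arr = np.vstack(trimmed)
    lag_grid = curves[int(np.argmin([c.values.size for c in curves]))].lags
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(m)
    return pd.DataFrame({"lag_s": lag_grid, "value": arr.mean(axis=0), "sem": sem})


# ---------------------------------------------------------------------------
# rate estimation


@dataclass
class RateEstimates:
    """Transition-rate summaries pooled over cells."""

    k_ccw_cw: float
    k_ccw_cw_se: float
    k_cw_ccw: float
    k_cw_ccw_se: float
    waveform_rates: pd.DataFrame  # columns: from_state, to_state, rate, se, n_transitions, dwell_s
    sequence_histogram: Dict[str, int] = field(default_factory=dict)


def _transitions_and_dwell(states: np.ndarray, step: float, n_states: int):
    """Counts[i, j] of i→j transitions and total dwell time per state."""
    counts = np.zeros((n_states, n_states), dtype=int)
    prev = states[:-1]
    nxt = states[1:]
    changed = prev != nxt
    for i, j in zip(prev[changed], nxt[changed]):
        counts[i, j] += 1
    dwell = np.array([np.sum(states == s) * step for s in range(n_states)])
    return counts, dwell


def _rate_and_se(n_trans: int, dwell: float) -> Tuple[float, float]:
    if dwell <= 0:
        return float("nan"), float("nan")
    rate = n_trans / dwell
    se = np.sqrt(n_trans) / dwell if n_trans > 0 else float("nan")
    return rate, se


def _episode_sequences(waveform: np.ndarray, motor: np.ndarray) -> Dict[str, int]:
    """Histogram of waveform sequences within CW episodes (N→S→N etc.)."""
    hist: Dict[str, int] = {}
    codes = {SEMI_COILED: "S", CURLY_1: "C"}
    padded = np.diff(np.concatenate(([0], (motor == CW).astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    for i, j in zip(starts, ends):
        seq = waveform[i:j]
        inner = "".join(codes[s] for k, s in enumerate(seq) if k == 0 or seq[k - 1] != s)
        key = "N" + inner + "N"
        hist[key] = hist.get(key, 0) + 1
    return hist


def estimate_rates(cells: Sequence) -> RateEstimates:
    """Motor and waveform transition rates pooled over cells.

    Each rate is (# transitions i→j) / (total dwell time in i), with a
    Poisson standard error sqrt(#transitions)/dwell.  Also returns the
    histogram of waveform sequences per CW episode.
    """
    motor_counts = np.zeros((2, 2), dtype=int)
    motor_dwell = np.zeros(2)
    wf_counts = np.zeros((3, 3), dtype=int)
    wf_dwell = np.zeros(3)
    seq_hist: Dict[str, int] = {}
    for cell in cells:
        motor = np.asarray(cell.motor)
        for f in range(cell.n_flag):
            c, d = _transitions_and_dwell(motor[f], cell.step, 2)
            motor_counts += c
            motor_dwell += d
            wf = getattr(cell, "waveform", None)
            if wf is not None:
                wf_arr = np.asarray(wf)
                c3, d3 = _transitions_and_dwell(wf_arr[f], cell.step, 3)
                wf_counts += c3
                wf_dwell += d3
                for key, n in _episode_sequences(wf_arr[f], motor[f]).items():
                    seq_hist[key] = seq_hist.get(key, 0) + n

    k_cc, k_cc_se = _rate_and_se(motor_counts[CCW, CW], motor_dwell[CCW])
    k_wc, k_wc_se = _rate_and_se(motor_counts[CW, CCW], motor_dwell[CW])

    rows = []
    names = {NORMAL: "normal", SEMI_COILED: "semi_coiled", CURLY_1: "curly_1"}
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            rate, se = _rate_and_se(wf_counts[i, j], wf_dwell[i])
            rows.append({
                "from_state": names[i], "to_state": names[j],
                "rate": rate, "se": se,
                "n_transitions": int(wf_counts[i, j]),
                "dwell_s": float(wf_dwell[i]),
            })
    return RateEstimates(
        k_ccw_cw=k_cc, k_ccw_cw_se=k_cc_se,
        k_cw_ccw=k_wc, k_cw_ccw_se=k_wc_se,
        waveform_rates=pd.DataFrame(rows),
        sequence_histogram=seq_hist,
    )


# ---------------------------------------------------------------------------
# independent-flagella null and filters


def independent_null(
    n_flag: int,
    cb: float,
    duration: float,
    model,
    seed=None,
    max_lag: float = 3.0,
):
    """Statistics of a matched cell with independently switching flagella.

    Simulates a constant-CB cell (no shared fluctuations) with the same
    flagellar number, CW bias and duration, and returns the per-cell
    summary, tumble events and (for n_flag >= 2) the pair
    cross-correlation — the null against which correlated switching is
    judged.
    """
    from . import flagella_sim

    record = flagella_sim.simulate_cell(
        model, n_flag=n_flag, duration=duration,
        strain_mode="constant_cb", cb_constant=cb, seed=seed,
        with_waveforms=False,
    )
    summary = summarize_cell(record)
    events = [e for e in tumble_events(record) if e.complete]
    xcorr = pair_cross_correlation(record, max_lag=max_lag) if n_flag >= 2 else None
    return {"summary": summary, "events": events, "cross_correlation": xcorr}


def filter_cells(
    summaries: Sequence[CellSummary],
    cb_interval: Tuple[float, float] = (0.0, 0.25),
) -> List[CellSummary]:
    """Keep cells with cb in (lo, hi]; outliers are logged and dropped.

    The lower bound is exclusive — cb = 0 cells carry no defined eta
    and are excluded from bias analyses.
    """
    lo, hi = cb_interval
    kept = [c for c in summaries if lo < c.cb <= hi]
    n_excluded = len(summaries) - len(kept)
    if n_excluded:
        logger.info(
            "filter_cells: excluded %d of %d cells outside CB range (%g, %g]",
            n_excluded, len(summaries), lo, hi,
        )
    return kept


def group_eta(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    """Mean eta per n_flag group (per-cell values averaged; SEM over cells)."""
    rows = [
        {"n_flag": c.n_flag, "eta": c.eta}
        for c in summaries
        if c.eta is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["n_flag", "eta_mean", "sem", "n_cells"])
    df = pd.DataFrame(rows)
    out = df.groupby("n_flag")["eta"].agg(eta_mean="mean", sem="sem", n_cells="count")
    return out.reset_index()
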