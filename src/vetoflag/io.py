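"""Plain-text dataset and table formats.

Flagellar state traces have no standard bioinformatics container, so
everything is TSV with a JSON manifest: per-cell summaries (one row
per cell), per-group fits, cross-correlation tables, long-format state
traces (time_s, flagellum_id, motor_state, waveform_state, run_state)
and a dataset manifest carrying the config, seed and per-file
checksums.  Timestamps are trace-relative seconds, 0-based, half-open.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import CellSummary, GroupFit
from .synthetic_data import ObservedCell, PopulationConfig

SCHEMA_VERSION = 1

CELL_TSV_COLUMNS = ["cell_id", "strain", "n_flag", "duration_s", "tb", "cb", "eta"]
GROUP_TSV_COLUMNS = ["n_flag", "n_eff", "r_squared", "n_cells"]


class SchemaError(ValueError):
    """A table does not match its expected column schema."""


def _check_columns(df: pd.DataFrame, expected: Sequence[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


# ---------------------------------------------------------------------------
# summary tables


def summaries_to_frame(cells: Sequence[CellSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "strain": c.strain,
                "n_flag": c.n_flag,
                "duration_s": c.duration_s,
                "tb": c.tb,
                "cb": c.cb,
                "eta": np.nan if c.eta is None else c.eta,
            }
            for c in cells
        ],
        columns=CELL_TSV_COLUMNS,
    )


def write_cell_summaries(cells: Sequence[CellSummary], path) -> None:
    summaries_to_frame(cells).to_csv(path, sep="\t", index=False)


def read_cell_summaries(path) -> List[CellSummary]:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, CELL_TSV_COLUMNS, str(path))
    out = []
    for row_num, r in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                CellSummary(
                    n_flag=int(r.n_flag), tb=float(r.tb), cb=float(r.cb),
                    eta=None if pd.isna(r.eta) else float(r.eta),
                    cell_id=str(r.cell_id), strain="" if pd.isna(r.strain) else str(r.strain),
                    duration_s=float(r.duration_s),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path} row {row_num}: {exc}") from exc
    return out


def write_group_fits(fits: Sequence[GroupFit], path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(f) for f in fits], columns=GROUP_TSV_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def read_group_fits(path) -> List[GroupFit]:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, GROUP_TSV_COLUMNS, str(path))
    return [
        GroupFit(n_flag=int(r.n_flag), n_eff=float(r.n_eff),
                 r_squared=float(r.r_squared), n_cells=int(r.n_cells))
        for r in df.itertuples(index=False)
    ]


def read_targets(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["statistic", "x", "value", "sem"], str(path))
    if (df["sem"] <= 0).any():
        bad = df.index[df["sem"] <= 0][0] + 2
        raise SchemaError(f"{path} row {bad}: sem must be > 0")
    return df


# ---------------------------------------------------------------------------
# observed-cell traces


def write_observed_cell(cell: ObservedCell, path) -> None:
    """Long-format TSV: one row per (window, flagellum)."""
    rows = []
    n_windows = cell.motor.shape[1]
    for w in range(n_windows):
        t = w * cell.window
        for f in range(cell.n_flag):
            rows.append({
                "time_s": round(t, 6),
                "flagellum_id": f,
                "motor_state": int(cell.motor[f, w]),
                "waveform_state": int(cell.waveform[f, w]) if cell.waveform is not None else -1,
                "run_state": int(cell.tumble[w]),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_observed_cell(path, cell_id: str = "", strain: str = "") -> ObservedCell:
    df = pd.read_csv(path, sep="\t")
    _check_columns(
        df, ["time_s", "flagellum_id", "motor_state", "waveform_state", "run_state"],
        str(path),
    )
    flagella = sorted(df["flagellum_id"].unique())
    times = np.sort(df["time_s"].unique())
    window = float(times[1] - times[0]) if times.size > 1 else 0.1
    n_flag = len(flagella)
    n_windows = times.size
    motor = np.zeros((n_flag, n_windows), dtype=np.int8)
    waveform = np.zeros((n_flag, n_windows), dtype=np.int8)
    tumble = np.zeros(n_windows, dtype=np.int8)
    pivot = df.sort_values(["flagellum_id", "time_s"])
    for k, f in enumerate(flagella):
        sub = pivot[pivot.flagellum_id == f]
        motor[k] = sub["motor_state"].to_numpy(dtype=np.int8)
        waveform[k] = sub["waveform_state"].to_numpy(dtype=np.int8)
    first = pivot[pivot.flagellum_id == flagella[0]]
    tumble[:] = first["run_state"].to_numpy(dtype=np.int8)
    has_wf = not (waveform < 0).any()
    return ObservedCell(
        cell_id=cell_id, n_flag=n_flag, motor=motor, tumble=tumble,
        waveform=waveform if has_wf else None,
        window=window, duration=n_windows * window, strain=strain,
    )


# ---------------------------------------------------------------------------
# dataset directories with manifest


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: PopulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def write_dataset(
    observed: Sequence[ObservedCell],
    outdir,
    config: Optional[PopulationConfig] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write one TSV per cell plus a JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for cell in observed:
        fname = f"{cell.cell_id or 'cell'}.tsv"
        fpath = outdir / fname
        write_observed_cell(cell, fpath)
        entries.append({
            "file": fname,
            "cell_id": cell.cell_id,
            "n_flag": int(cell.n_flag),
            "duration_s": float(cell.duration),
            "strain": cell.strain,
            "sha256": _file_checksum(fpath),
        })
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n_cells": len(entries),
        "seed": seed,
        "config": _config_dict(config) if config is not None else None,
        "cells": entries,
    }
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return mpath


def read_dataset(path) -> List[ObservedCell]:
    """Read a dataset directory (or its manifest.json) back into memory."""
    path = Path(path)
    mpath = path / "manifest.json" if path.is_dir() else path
    with open(mpath) as fh:
        manifest = json.load(fh)
    base = mpath.parent
    cells = []
    for entry in manifest["cells"]:
        cells.append(
            read_observed_cell(
                base / entry["file"], cell_id=entry["cell_id"],
                strain=entry.get("strain", ""),
            )
        )
    return cells
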