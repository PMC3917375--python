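"""Figure-style reproductions from fresh synthetic cohorts.

Each entry simulates matched fluctuating ("wild-type-like") and
constant-CB ("CheY*-like") cohorts, computes the corresponding
analysis, writes its table(s) as TSV and a PNG plot, and returns the
written paths.  Tables are bit-identical across runs at a fixed seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import model_core, synthetic_data, trace_analysis


def _cohort(strain_mode: str, seed: int, cells_per_group: int):
    cfg = synthetic_data.PopulationConfig(
        n_cells=cells_per_group * 5,
        nflag_values=tuple(np.repeat([1, 2, 3, 4, 5], cells_per_group)),
        strain_mode=strain_mode,
        with_waveforms=False,
    )
    observed, _ = synthetic_data.sample_population(cfg, seed=seed)
    summaries = [trace_analysis.summarize_cell(c) for c in observed]
    kept = trace_analysis.filter_cells(summaries, (0.0, 0.25))
    return observed, summaries, kept


def _group_fits(kept):
    fits = []
    for n_flag in sorted({c.n_flag for c in kept}):
        group = [c for c in kept if c.n_flag == n_flag]
        if sum(1 for c in group if c.eta_defined) >= 2:
            fits.append(model_core.fit_n_eff(group))
    return fits


def reproduce(figure: str, outdir: Path, seed: int = 0, cells_per_group: int = 40) -> List[Path]:
    wt_obs, wt_all, wt = _cohort("wildtype_fluctuating", seed, cells_per_group)
    cc_obs, cc_all, cc = _cohort("constant_cb", seed + 1, cells_per_group)
    written: List[Path] = []

    def save(df: pd.DataFrame, name: str):
        p = outdir / f"{figure}_{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)

    def save_fig(fig, name: str):
        p = outdir / f"{figure}_{name}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    if figure in ("fig1e", "fig4c"):
        wt_eta = trace_analysis.group_eta(wt).assign(strain="fluctuating")
        cc_eta = trace_analysis.group_eta(cc).assign(strain="constant")
        df = pd.concat([wt_eta, cc_eta])
        save(df, "eta_vs_nflag")
        fig, ax = plt.subplots()
        for label, sub in df.groupby("strain"):
            ax.errorbar(sub.n_flag, sub.eta_mean, yerr=sub["sem"], marker="o",
                        linestyle="-", label=label)
        ax.axhline(0, color="gray", linestyle="--")
        ax.set_xlabel("flagella per cell")
        ax.set_ylabel(r"deviation from veto model $\eta$")
        ax.legend()
        save_fig(fig, "eta_vs_nflag")

    elif figure == "fig2c":
        wt_df = trace_analysis.mean_max_cw(wt_obs).assign(strain="fluctuating")
        cc_df = trace_analysis.mean_max_cw(cc_obs).assign(strain="constant")
        df = pd.concat([wt_df, cc_df])
        save(df, "max_cw")
        fig, ax = plt.subplots()
        for label, sub in df.groupby("strain"):
            ax.errorbar(sub.n_flag, sub.mean_max_cw, yerr=sub["sem"], marker="o", label=label)
        ax.plot([1, 5], [1, 5], color="gray", linestyle=":", label="all flagella")
        ax.set_xlabel("flagella per cell")
        ax.set_ylabel("mean max CW flagella per tumble")
        ax.legend()
        save_fig(fig, "max_cw")

    elif figure == "fig2d":
        wt_df = trace_analysis.population_cross_correlation(wt_obs, max_lag=3.0).assign(strain="fluctuating")
        cc_df = trace_analysis.population_cross_correlation(cc_obs, max_lag=3.0).assign(strain="constant")
        df = pd.concat([wt_df, cc_df])
        save(df, "cross_correlation")
        fig, ax = plt.subplots()
        for label, sub in df.groupby("strain"):
            ax.plot(sub.lag_s, sub.value, label=label)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("pair cross-correlation")
        ax.legend()
        save_fig(fig, "cross_correlation")

    elif figure in ("fig3a", "fig3b"):
        kept = wt if figure == "fig3a" else cc
        rows = [{"n_flag": c.n_flag, "cb": c.cb, "tb": c.tb} for c in kept]
        df = pd.DataFrame(rows)
        save(df, "tb_vs_cb")
        fits = _group_fits(kept)
        fig, ax = plt.subplots()
        cb_grid = np.linspace(0, 0.3, 100)
        for f in fits:
            sub = df[df.n_flag == f.n_flag]
            pts = ax.scatter(sub.cb, sub.tb, s=12, label=f"N={f.n_flag}")
            color = pts.get_facecolor()[0]
            ax.plot(cb_grid, model_core.veto_tumble_bias(cb_grid, f.n_flag),
                    linestyle="--", color=color, alpha=0.5)
            ax.plot(cb_grid, model_core.veto_tumble_bias(cb_grid, f.n_eff),
                    linestyle="-", color=color, alpha=0.8)
        ax.set_xlabel("CW bias")
        ax.set_ylabel("tumble bias")
        ax.legend(fontsize=8)
        save_fig(fig, "tb_vs_cb")

    elif figure == "fig3c":
        wt_fits = _group_fits(wt)
        cc_fits = _group_fits(cc)
        df = pd.concat([
            pd.DataFrame([vars(f) for f in wt_fits]).assign(strain="fluctuating"),
            pd.DataFrame([vars(f) for f in cc_fits]).assign(strain="constant"),
        ])
        save(df, "neff_vs_nflag")
        fig, ax = plt.subplots()
        for label, sub in df.groupby("strain"):
            ax.plot(sub.n_flag, sub.n_eff, marker="o", label=label)
        ax.plot([1, 5], [1, 5], color="gray", linestyle=":")
        ax.set_xlabel("flagella per cell")
        ax.set_ylabel(r"$N_{eff}$")
        ax.legend()
        save_fig(fig, "neff_vs_nflag")

    elif figure == "fig3d":
        wt_fits = {f.n_flag: f.n_eff for f in _group_fits(wt)}
        rows = []
        for c in wt:
            if c.eta_defined and c.n_flag in wt_fits:
                rows.append({"strain": "fluctuating", "x": (1 - c.cb) ** wt_fits[c.n_flag],
                             "y": 1 - c.tb})
        for c in cc:
            if c.eta_defined:
                rows.append({"strain": "constant", "x": (1 - c.cb) ** c.n_flag,
                             "y": 1 - c.tb})
        df = pd.DataFrame(rows)
        save(df, "collapse")
        fig, ax = plt.subplots()
        for label, sub in df.groupby("strain"):
            ax.scatter(sub.x, sub.y, s=10, label=label)
        lim = np.linspace(0, 1, 10)
        ax.plot(lim, lim, color="gray", linestyle="--")
        ax.set_xlabel(r"$(1-CB)^{N_{eff}}$")
        ax.set_ylabel("1 - TB")
        ax.legend()
        save_fig(fig, "collapse")

    return written
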