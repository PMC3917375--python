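#!/usr/bin/env python
"""Effective flagellar number N_eff and its power-law summary.

Per flagellar-number group, fits the generalized veto curve
1 - TB = (1 - CB)^N_eff across cells by least squares, then fits
N_eff = a·N_flag^b across groups in log-log space.

Expected finding: the constant-CheY-P control gives N_eff ≈ N_flag,
while the fluctuating cohort gives N_eff well below N_flag and a
sublinear power law.  The power law is reported both over all groups
and over the multi-flagellated groups only: for simulated cells
TB ≡ CB when N_flag = 1 (one shared measurement channel), pinning
N_eff(1) = 1 by construction, so the all-group fit is dragged toward
a = 1.

Writes results/neff_{cohort}.tsv and results/power_law.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from vetoflag import filter_cells, fit_n_eff, fit_power_law, io, summarize_cell

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> int:
    power_rows = []
    for name in ("fluctuating", "constant"):
        ds = RESULTS / "datasets" / name
        if not ds.exists():
            print(f"missing dataset {ds}; run 01_simulate_cohorts.py first")
            return 1
        cells = io.read_dataset(ds)
        summaries = filter_cells([summarize_cell(c) for c in cells], (0.0, 0.25))
        fits = []
        for n_flag in sorted({c.n_flag for c in summaries}):
            group = [c for c in summaries if c.n_flag == n_flag]
            if sum(1 for c in group if c.eta_defined) >= 2:
                fits.append(fit_n_eff(group))
        io.write_group_fits(fits, RESULTS / f"neff_{name}.tsv")
        print(f"\n{name} cohort N_eff per group:")
        for f in fits:
            print(f"  N_flag={f.n_flag}: N_eff={f.n_eff:.2f} "
                  f"(R²={f.r_squared:.2f}, n={f.n_cells})")
        for label, subset in (
            ("all_groups", fits),
            ("multiflagellated", [f for f in fits if f.n_flag >= 2]),
        ):
            if len({f.n_flag for f in subset}) >= 2:
                pl = fit_power_law(subset)
                power_rows.append({"cohort": name, "groups": label,
                                   "a": round(pl.a, 4), "b": round(pl.b, 4)})
                print(f"  power law ({label}): N_eff = {pl.a:.3f} · N^{pl.b:.3f}")
    pd.DataFrame(power_rows).to_csv(RESULTS / "power_law.tsv", sep="\t", index=False)
    return 0


if __name__ == "__main__":
    sys.exit(main())
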