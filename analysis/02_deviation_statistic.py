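#!/usr/bin/env python
"""Per-cell biases and the deviation statistic η for both cohorts.

For every cell: tumble bias TB, mean CW bias CB, and
η = log(1-TB)/log(1-CB) - N_flag.  η ≈ 0 means the cell behaves like
N independent flagella under the veto rule; η < 0 means it tumbles
less, i.e. its flagella switch together.

Expected finding: the constant-CheY-P cohort sits at η ≈ 0 for every
flagellar number, while the fluctuating cohort grows increasingly
negative with flagellar number.

Writes results/cells_{cohort}.tsv and results/eta_{cohort}.tsv.
"""

import sys
from pathlib import Path

from vetoflag import filter_cells, group_eta, io, summarize_cell

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> int:
    for name in ("fluctuating", "constant"):
        ds = RESULTS / "datasets" / name
        if not ds.exists():
            print(f"missing dataset {ds}; run 01_simulate_cohorts.py first")
            return 1
        cells = io.read_dataset(ds)
        summaries = [summarize_cell(c) for c in cells]
        io.write_cell_summaries(summaries, RESULTS / f"cells_{name}.tsv")
        kept = filter_cells(summaries, (0.0, 0.25))
        table = group_eta(kept)
        table.to_csv(RESULTS / f"eta_{name}.tsv", sep="\t", index=False)
        print(f"\n{name} cohort ({len(kept)}/{len(summaries)} cells in CB range):")
        print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    return 0


if __name__ == "__main__":
    sys.exit(main())
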