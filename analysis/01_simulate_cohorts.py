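#!/usr/bin/env python
"""Simulate the two study cohorts and write them as TSV datasets.

Cohort A ("wild-type-like"): CheY-P concentration fluctuates as an OU
process and drives all flagella on a cell through the shared Hill
response — flagella switch in a correlated way.

Cohort B ("CheY*-like" control): CheY-P is constant per cell, so
flagella switch independently at the cell's CW bias.

Both cohorts share the population structure of trapped-cell
experiments: 1-5+ flagella per cell, per-cell CW bias 0.11 ± 0.07
restricted to (0, 0.25], durations 8-40 s, and 100-ms observation
windows.  Output: results/datasets/{fluctuating,constant}/ with one
TSV per cell plus a manifest.
"""

import sys
from pathlib import Path

import numpy as np

from vetoflag import PopulationConfig, io, sample_population

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "datasets"
SEED = 20260928
CELLS_PER_GROUP = 30
GROUPS = (1, 2, 3, 4, 5)


def main() -> int:
    for name, strain in (("fluctuating", "wildtype_fluctuating"),
                         ("constant", "constant_cb")):
        cfg = PopulationConfig(
            n_cells=CELLS_PER_GROUP * len(GROUPS),
            nflag_values=tuple(np.repeat(GROUPS, CELLS_PER_GROUP)),
            strain_mode=strain,
        )
        observed, _ = sample_population(cfg, seed=SEED)
        manifest = io.write_dataset(observed, OUT / name, config=cfg, seed=SEED)
        n_windows = sum(o.motor.shape[1] for o in observed)
        print(f"{name}: {len(observed)} cells, {n_windows} observation windows "
              f"-> {manifest.parent}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
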