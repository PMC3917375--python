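# vetoflag

Stochastic simulation and analysis linking single-flagellum motor
switching to whole-cell run/tumble swimming in *E. coli*.

Peritrichous bacteria swim by bundling several helical flagella; the
cell *runs* while every flagellar motor turns counter-clockwise (CCW)
and *tumbles* when motors switch clockwise (CW) and disrupt the
bundle.  The **veto model** states that a single CW flagellum is
enough to interrupt a run, so for a cell with `N` independently
switching flagella of clockwise bias `CB` (the fraction of time a
motor spends CW), the tumble bias `TB` (fraction of time tumbling) is

```
TB = 1 − (1 − CB)^N
```

This package implements, as tested reusable code, the computational
pipeline used to probe that relation in single cells:

- **Deviation statistic** `η = log(1−TB)/log(1−CB) − N`: zero for
  independent flagella under the veto rule, negative when flagella
  switch in a *correlated* way (the cell tumbles less than `N`
  independent flagella would make it).
- **Effective flagellar number** `N_eff`, the exponent fitted per
  flagellar-number group in the generalized relation
  `1 − TB = (1 − CB)^N_eff`, with an empirical power-law summary
  `N_eff = a · N^b` across groups.
- **Intracellular noise model**: CheY-P concentration `Y(t)` follows a
  mean-reverting Ornstein–Uhlenbeck process
  `Y(t+dt) = Y(t) − (Y(t) − ⟨Y⟩)/τ · dt + A·ξ`, mapped to an
  instantaneous CW bias through the steep Hill response
  `CB(Y) = Y^H / (K_d^H + Y^H)` (`K_d = 3.1 µM`, `H = 10.3`).  Because
  one CheY-P pool drives all motors on a cell, slow concentration
  fluctuations switch flagella in near-synchrony — the proposed origin
  of `η < 0`.
- **Motor model**: each flagellum is a two-state telegraph process
  with rates `k_CCW→CW = CB(t)/ω` and `k_CW→CCW = (1 − CB(t))/ω`
  (`ω = 0.5 s`), plus a 3-state filament waveform overlay
  (*normal* / *semi-coiled* / *curly-1*) and run-rule variants.
- **Trace analysis**: per-cell TB/CB estimation from 100-ms windowed
  state calls, tumble segmentation with the maximum number of
  simultaneously CW flagella per tumble, pairwise cross-correlation of
  flagellar states, transition-rate estimation, and the
  independent-flagella null.
- **Calibration**: grid scan of the two free fluctuation parameters
  (σ², τ) minimizing a global reduced χ² over four summary statistics.
- **Synthetic cohorts**: a generator emulating trapped-cell
  measurements (flagellar numbers 1–5+, per-cell CW bias 0.11 ± 0.07,
  8–40 s traces, windowed observations) so the full pipeline runs
  without any experimental download.

## Worked example

Simulate matched cohorts (150 cells each) and measure the deviation
statistic and effective flagellar numbers:

```
python analysis/01_simulate_cohorts.py
python analysis/02_deviation_statistic.py
python analysis/03_effective_flagella.py
```

`02` prints, for the fluctuating-CheY-P ("wild-type-like") cohort:

```
 n_flag  eta_mean   sem  n_cells
      1     0.000 0.000       28
      2    -0.199 0.049       26
      3    -0.483 0.080       29
      4    -1.124 0.119       29
      5    -1.569 0.176       27
```

η falls steadily below zero as flagella are added — shared CheY-P
fluctuations make flagella switch together, so multi-flagellated cells
tumble far less than the veto prediction.  The constant-CheY-P control
cohort stays within error of `η = 0` for every group (its flagella
switch independently).  `03` turns the same cohorts into effective
flagellar numbers; for the fluctuating cohort:

```
  N_flag=2: N_eff=1.65 (R²=0.94, n=26)
  N_flag=3: N_eff=2.29 (R²=0.96, n=29)
  N_flag=4: N_eff=2.59 (R²=0.74, n=29)
  N_flag=5: N_eff=3.30 (R²=0.74, n=27)
```

so a five-flagellated wild-type-like cell behaves like roughly three
independent flagella, while the control cohort gives `N_eff ≈ N`.
`analysis/04_tumble_structure.py` adds the tumble-anatomy views (max
CW flagella per tumble, pair cross-correlation ≈ 0.26 at lag 0 for the
fluctuating cohort vs ≈ 0 for the control) and
`analysis/05_calibrate_fluctuations.py` demonstrates the reduced-χ²
calibration of (σ², τ).

The same steps are available as a CLI
(`vetoflag simulate / analyze / fit / reproduce`); see
`vetoflag --help`.

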