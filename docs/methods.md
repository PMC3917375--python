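# Methods

## Model

A cell carries `N` flagellar motors, each a two-state continuous-time
telegraph process over {CCW, CW}.  The instantaneous switching rates
are set by the shared intracellular signal through the clockwise bias
`CB(t) ∈ [0, 1]`:

    k_CCW→CW(t) = CB(t) / ω,        k_CW→CCW(t) = (1 − CB(t)) / ω,

so the conditional CW occupancy of each motor relaxes toward `CB(t)`
with a constant total rate `1/ω` and the stationary occupancy equals
the bias.  At the wild-type operating point (`CB = 0.13`, `ω = 0.5 s`)
the rates are 0.26 s⁻¹ and 1.74 s⁻¹ and the mean CW and CCW dwell
times are `ω/(1−CB) ≈ 0.57 s` and `ω/CB ≈ 3.8 s`.

The signal is phosphorylated CheY.  Its concentration `Y(t)` follows a
discretized Ornstein–Uhlenbeck process,

    Y(t+dt) = Y(t) − (Y(t) − ⟨Y⟩)/τ · dt + A·ξ,   ξ ~ N(0,1),

clipped at zero, and maps to the bias through a Hill function
`CB = Y^H / (K_d^H + Y^H)`.  With `H = 10.3` the response is nearly
switch-like around `K_d = 3.1 µM`: when a shared upward excursion of
`Y(t)` crosses the response region, every motor on the cell sees a
near-unity bias at the same time.  This is the mechanism that
correlates flagella — and the only coupling in the model; motors are
conditionally independent given `CB(t)`.

Run/tumble behaviour follows from a run rule.  The default is the
veto rule: the cell runs at time `t` iff every flagellum is CCW.  Two
variants are implemented for sensitivity analyses: the X-rule (a run
requires ≥ X *normal* flagella with every CW flagellum in *curly-1*)
and the curly-run rule (an interval with exactly one curly-1 flagellum
and all others normal is relabelled a run with probability 0.18, one
Bernoulli draw per maximal interval, which reproduces an 18% run-time
fraction in expectation).  Both are off by default; the headline
analyses use the plain veto rule.

Filament waveforms are overlaid on the binary motor trace as a
within-CW-interval Markov chain: CCW ⇒ *normal*; a CCW→CW switch
enters *semi-coiled* or *curly-1* with probabilities proportional to
the measured normal-exit rates (0.28 and 0.08 s⁻¹, i.e. 22% direct
curly-1 entries); semi-coiled converts irreversibly to curly-1 at
0.68 s⁻¹ within the interval; CW→CCW restores *normal*.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| CB | mean wild-type motor bias | 0.13 | – |
| ω | characteristic motor switching time | 0.5 | s |
| ⟨Y⟩ | mean CheY-P concentration | 2.59 | µM |
| σ² | variance of CheY-P fluctuations | 1.0 | µM² |
| τ | fluctuation timescale | 5.0 | s |
| K_d, H | Hill midpoint / coefficient | 3.1, 10.3 | µM, – |
| λ | semi-coiled → curly-1 rate | 0.68 | s⁻¹ |
| dt | simulation step | 0.001 | s |

Two of these need justification because the quantities they derive
from are quoted in the field under conflicting conventions.

**Fluctuation timescale τ.**  The fitted CheY-P fluctuation scale is
quoted both as a time ("0.2 s") and as a rate ("0.2 s⁻¹", i.e.
τ = 5 s).  We adopt τ = 5 s.  The 0.2 s reading fails on two
independent grounds.  First,
with τ = 0.2 s ≪ ω = 0.5 s the motors low-pass the fluctuations away:
simulated cohorts show essentially no inter-flagellar correlation
(pair correlation ≈ 0.01, `N_eff ≈ N`), so none of the phenomena the
model exists to explain occur.  Second, the described trace-acceptance
step (below) becomes statistically impossible: the probability that a
trace of the stated 8–40 s duration passes the bias band is below
10⁻⁴ (we measured 0 acceptances in 30 000 attempts at 16 s and
longer), so the described simulation procedure cannot terminate.  At
τ = 5 s both problems vanish and all reported phenomena emerge.

**Noise amplitude.**  The update rule as printed has per-step
amplitude `A = sqrt(σ² dt/τ)`, whose stationary variance is σ²/2 —
half the value the parameter table calls "variance in [CheY-P]".  The
package default is `variance_matched` (`A = sqrt(2 σ² dt/τ)`), which
makes the realized variance equal σ², matching the table's meaning;
the `verbatim` mode is provided and both are unit-tested against
their closed-form stationary variances.

**Trace acceptance.**  Candidate CheY-P traces are accepted only if
their mean CW bias — the time-average of the instantaneous
Hill-transformed bias — lies in a band, regenerating with fresh noise
up to 1000 attempts (then an error carrying the attempted-mean
distribution).  For a homogeneous cohort the band is [0.13, 0.145];
when per-cell bias heterogeneity is on (the default), the band is
centred on each cell's target bias with the same half-width (0.0075).

## Synthetic cohorts

The generator emulates optically-trapped-cell measurements: flagellar
number from a zero-truncated Poisson (mean 3.4, a stand-in
convention; group sizes can be fixed explicitly), trace durations
uniform on 8–40 s (the photobleaching window), per-cell CW-bias
targets from a normal with mean 0.11 and SD 0.07 truncated to
(0, 0.25], and per-flagellum/run-tumble state calls as majority votes
in 100-ms observation windows (ties carry the previous call).
Per-cell heterogeneity is realized by inverting the Hill map to set
each cell's ⟨Y⟩ (default) or by population-level trace acceptance at
a global ⟨Y⟩.

What the generator does *not* emulate — and hence what passing tests
cannot show about real data: TB and CB are measured from the same
simulated state series, whereas experiments measure them through
independent channels (trap signal vs fluorescence imaging) with
independent errors; there is no manual-classification noise (an
optional per-window misclassification probability exists, default 0,
as an estimator stress test only); no hydrodynamic coupling between
flagella; no photophysics.  One structural consequence: for a
single-flagellum simulated cell TB ≡ CB exactly, so `N_eff(1) = 1`
identically, while experimental single-flagellum estimates scatter
freely around 1.  For this reason the power-law summary
`N_eff = a·N^b` of simulated cohorts is fitted over the
multi-flagellated groups (N ≥ 2) by default; the all-group fit is
also reported by the analysis scripts.

## Estimators and numerical choices

- Per-cell CB: per-flagellum CW time-fraction, unweighted mean over
  flagella.  Per-cell TB: tumble time-fraction.  η is computed per
  cell and averaged within flagellar-number groups (SEM over cells);
  cells with measured CB ∈ {0, 1} or TB = 1 are excluded with a
  warning, and bias analyses keep cells with CB in (0, 0.25].
- `N_eff` per group minimizes the sum of squared TB-residuals on
  (0, 20] (bounded scalar minimization, cross-checked against a 10⁻⁴
  grid search in tests); a log-space variant (regression of
  log(1−TB) on log(1−CB) through the origin) is exposed as an option.
  A single cell uses the closed form log(1−TB)/log(1−CB).
- The power law is an unweighted least-squares line in log-log space.
- Tumble events are maximal contiguous tumble intervals; events
  touching a trace boundary are censored and excluded from max-CW
  statistics.  The group statistic averages over complete events
  (SEM over events); a per-cell-first variant exists and is used in
  calibration, where within-cell event correlation would otherwise
  understate the uncertainty.
- Pair cross-correlation: per flagellum mean-subtracted binary CW
  indicators, Pearson-normalized per pair, overlap-normalized lags
  (positive lag = second flagellum delayed), averaged over unordered
  pairs, then over cells; zero-variance flagella are skipped with a
  warning.  The definition is a documented package choice.
- Motor and waveform transition rates are (# transitions)/(dwell
  time) with Poisson standard errors; observation windows are treated
  as exact state calls.
- Simulation uses fixed-step Euler–Bernoulli switching at dt = 1 ms
  (per-step probability rate·dt, guarded by rate·dt ≤ 0.1) rather
  than exact Gillespie sampling, matching the 1 ms resolution of the
  modelled pipeline; the OU recursion is evaluated as an AR(1) filter.
  Motor initial states are drawn from the instantaneous bias at t = 0.
  Every cell uses spawned child RNG streams (one per flagellum plus
  one for the drive), so cohorts are bitwise reproducible and adding
  a flagellum does not perturb the other trajectories.

## Calibration

The two free parameters (σ², τ) are fitted by scanning a grid; each
point simulates a population with common random numbers and scores
four summaries against target tables — mean max-CW per tumble vs N,
the cross-correlation curve, N_eff vs N, and η vs N — by reduced χ²
with dof = (#points − 2) per component, summed into a global value.
Residuals are normalized by the combined uncertainty
sqrt(sem_target² + sem_sim²), since both sides are Monte-Carlo
estimates.  The default grid (σ² ∈ {0.25…2.0} step 0.25,
τ ∈ {1…10} s step 1) contains the package's default optimum
(1.0 µM², 5 s) exactly.

A caveat established by the self-recovery analysis
(`analysis/05_calibrate_fluctuations.py`): at realistic cohort sizes
(tens to a few hundred cells) the χ² surface has a shallow ridge
along σ²/τ ≈ constant — amplitude and timescale trade off in the
near-adiabatic regime — so single-realization minima wander within
the ridge by more than one grid step even though the generating point
lies in the basin.  Sharper recovery requires either much larger
cohorts or summaries that probe lags well beyond τ.

## Known limitations

- The estimator of η is biased upward by ~0.05–0.08 on 8–40 s traces
  (Jensen curvature of log(1−TB) under sampling noise); the bias is a
  property of the per-cell estimator itself, shared by any analysis
  of traces this short, and is visible in the constant-CheY-P control
  cohort.
- The simulated `N_eff(N)` curve at the default parameters is
  somewhat steeper than the square-root law that summarizes
  experimental cohorts (simulated exponent ≈ 0.65–0.72 over N = 2–5):
  shared OU fluctuations filtered through the finite motor response
  under-correlate five-flagellated cells relative to data.
  Mechanisms deliberately out of scope (e.g. hydrodynamic coupling,
  which grows with flagellar number) act in the missing direction.
- Curly-2 waveforms, bundle mechanics, swimming trajectories and
  receptor-level kinetics are not modelled.
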