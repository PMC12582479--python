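# Methods

## The decomposition model

`thermoload` separates repeated-measures psychophysiological time series
recorded under alternating room temperatures into three latent components.
Four experimental conditions share one session protocol: a control with no
temperature step (both rooms at 26 °C) and three step conditions
(26–31 °C, 26–36 °C, 21–36 °C).  For a modality observed at time points
t = 1…T, the observation equations are

```
y_a(t) = Base_t + ε_a                              (control, a = T_26-26)
y_n(t) = Base_t + Load_{t,n} + Env_{t,n} + ε_n     (n = b, c, d)
ε_n ~ Normal(0, σ_n)
```

with the state equations

```
Base_t     = 2·Base_{t-1}   − Base_{t-2}   + ε_Base,t      ε_Base ~ Normal(0, σ_Base)
Load_{t,n} = 2·Load_{t-1,n} − Load_{t-2,n} + ε_Load,t      ε_Load ~ Cauchy(0, σ_Load)
Env_{t,n}  = −h · Σ_{k=t-N+1}^{t-1} Env_{k,n} + ε_Env,t    ε_Env  ~ Normal(0, σ_Env)
```

*Base* is a second-order random walk (locally linear trend) common to all
conditions: it absorbs drift caused by time passage alone, and is
identified by the control condition.  *Load* is a per-condition locally
linear trend with Cauchy innovations, capturing the accumulated burden of
repeated temperature steps; the heavy tails admit occasional abrupt
shifts.  *Env* is a damped seasonal term synchronized with the room
alternation: a free damping factor h ∈ (0, 1] relaxes the usual exact
zero-sum seasonal constraint (h = 1).  N, the seasonal summation length,
is the number of grid points per consecutive B+A room pair — 8 for skin
temperature, 6 for the HRV modalities, 8 for the fatigue ratings — and is
overridable per series.

A *prediction* variant replaces the Cauchy Load innovations with Normal
ones and drops the Env damping (h fixed at 1).  It is used for the
truncate-and-forecast analysis, where the model is fitted to the first
three room cycles and the fourth is predicted.  A flag (`retain_h`)
samples h in forecast mode instead.

Missing observations contribute no likelihood term; their latent
predicted means are sampled like any other state, so imputation is free.

The model is fitted to one modality at a time, by default to the
across-participant mean series per condition; a per-participant analysis
reuses the same density independently per subject.

## Priors and initial conditions

The model text leaves priors open, so the package uses weakly-informative
defaults, all configurable through `PriorConfig`:

* every scale σ gets a half-Normal(0, s) prior with s = 2.5 × sd(y) by
  default (`PriorConfig.from_data`);
* h is Uniform(0, 1];
* the initial states (Base and Load at t = 1, 2; the first N−1 Env values)
  get Normal priors centred on the first observations — Base on the first
  control value, Load on the first condition-minus-control gap, Env on
  zero — with a wide common scale (10 × s by default).

Cauchy innovations are the full two-sided distribution, not half-Cauchy.
σ_Load and σ_Env are shared across the three step conditions (their
symbols carry no condition subscript); the state dimension and term
bookkeeping would accept per-condition scales without structural change.

## Posterior computation

The sampler is written for this model rather than delegated to a generic
PPL, exploiting its conditional linear-Gaussian structure.  Conditional on
the noise scales, the damping factor and — for the Cauchy variant —
per-innovation auxiliary variances (a Cauchy is a normal scale mixture
with inverse-gamma mixing), the full state vector is jointly Gaussian, so
its marginal likelihood is available in closed form from one Cholesky
factorization of the joint state precision.  Each iteration:

1. **Hyperparameters, states integrated out.**  Every log-scale (four
   observation scales, σ_Base, σ_Load, σ_Env) and h is updated by Neal's
   stepping-out/shrinkage slice sampler targeting the state-marginal
   posterior; two additional slice updates along random directions in the
   joint log-scale space track posterior correlations among the scales.
   Slice widths adapt toward three times the typical accepted move during
   warm-up and are frozen afterwards.
   Because no update conditions on the states, hyperparameter draws are
   nearly uncorrelated — the property that lets the standard budget
   (4 chains × 2000 + 2000) reach effective sample sizes above 1000.
2. **States.**  All 7T latent values (Base, three Loads, three Envs) are
   drawn exactly from their joint Gaussian full conditional.  States are
   interleaved by time so the precision matrix is banded with bandwidth
   max(14, 7(N−1)); assembly uses precomputed flat indices into LAPACK
   banded storage (one `bincount`), and factorization/solves use
   `cholesky_banded`.  The same factorization yields the marginal
   log-likelihood (log-determinant plus completed square), the posterior
   mean and the random draw.
3. **Cauchy mixture.**  Given the states, (σ_Load, mixture shapes) are
   redrawn as a block: σ_Load from its conditional with the mixture
   integrated out (a Cauchy likelihood on the Load second differences,
   1-D slice update), then the inverse-gamma shapes conjugately.  The
   shapes are parameterized scale-free (λ = σ_Load²·ξ) so σ_Load also
   moves marginally of the states in step 1.

Correctness of the banded assembly is pinned to the independently coded
joint density: the identity
log p(y|θ) + log N(z | μ, Q⁻¹) = log p(y, z | θ) is asserted in the test
suite at 1e-7 for random states z.

Chains are initialized from data-scaled jittered values; warm-up draws
are discarded without adaptation (the slice sampler needs none).  All
randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawns, one stream per chain, so runs are
reproducible draw-for-draw.

## Diagnostics and comparisons

`rhat` and `ess` wrap ArviZ's rank-normalized split R-hat and bulk ESS;
constant chains return NaN (the diagnostics are undefined there).  The
package's convergence conventions are R-hat < 1.05 and ESS > 1000 for
every sampled hyperparameter, stored as `RHAT_THRESHOLD`/`ESS_THRESHOLD`.

Credible bands are central quantile intervals per time point; both 50%
and 95% levels are first-class (`level` parameter).  Two conditions are
declared *separated* at a time point when their closed credible intervals
are disjoint — touching endpoints count as overlapping.  This interval-
overlap rule is a decision convention, not a calibrated test; the package
exposes the verdict and leaves interpretation to the analyst.

Forecasting masks all observations after the split index, fits the
prediction variant, and forms posterior-predictive bands for the held-out
points *including observation noise*, so bands are comparable to future
measured values; the coverage fraction of held-out observations is
reported alongside.

## Protocol grids

The packaged session layout is: 6-min preparation, 14-min A_pre, seven
21-min blocks alternating rooms B and A (four B visits), 14-min A_post
(181 min of listed sections; the protocol's printed total of 183 min is
not forced, since the listed section durations do not reproduce it
exactly).  Skin temperature is averaged over 3 equal sub-ranges in
A_pre/A_post and 4 in each 21-min block (34 points); HRV gets one point
per 5-min rest block (1 + 3×7 + 1 = 23); fatigue ratings one per
questionnaire block (1 + 1 + 4×7 + 1 = 31).  The per-section rest and
questionnaire placements are not enumerated in the protocol figure
beyond these totals; the packaged plan spaces them uniformly within each
section and is overridable in `ProtocolSpec`.  Averaging sub-ranges are
half-open `[start, end)` with the final one closed, partitioning each
section exactly; grid indices are 1-based.

## HRV preprocessing

Rest windows drop their first 30 s (a 5-min rest yields 4.5 min of
beats).  HR is 60000 divided by the mean R-R interval in ms.  For band
powers the tachogram is cubic-spline resampled to an even 4 Hz grid,
linearly detrended, and fitted with a Burg (maximum-entropy) AR model of
order 16; LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) powers are the
integrals of the one-sided AR spectrum over the bands.  Resampling rate
and order are configurable; band *dominance* is stable across orders
8–30 (asserted against an integrated-periodogram oracle), while absolute
band power depends mildly on the order, which is why the package's own
checks avoid absolute-power assertions.  HF is reported as a natural log
and LF/HF as log LF − log HF (the log base is configurable; changing it
rescales linearly).  Ectopic-beat filtering is not applied by default —
input series are assumed clean.

## Synthetic data

`generate_dataset` produces ground-truth-known datasets on any protocol
grid, in three scenarios on a unit-magnitude scale (the scale of the log
spectral indices):

* `null` — all conditions share Base (Load = Env = 0);
* `step_load` — Load ramps to final magnitudes 1.0 / 2.5 / 3.0 for the
  5/10/15-degree conditions plus an integrated heavy-tailed wiggle, and
  Env oscillates with the room cycle (half-amplitudes 0.5 / 1.0 / 1.5);
* `cooling` — as `step_load` but the largest-step condition's Load is
  attenuated to 1.2, below the 10-degree condition.

Default noise scales are σ_obs = 0.5 per condition, σ_Base = 0.10,
σ_Load = 0.08, σ_Env = 0.10, h = 0.5.  Two generator-only
regularizations keep trajectories physiological and scenario orderings
guaranteed: Cauchy Load innovations are truncated at 6 scale units
(recorded in the truth file; fits never truncate), and the integrated
scenario wiggle is capped at 0.2, half the smallest between-condition
amplitude gap.  `model_dataset` instead simulates the state recursions
verbatim (with the same Cauchy truncation) for well-specified
recovery and convergence experiments.  Raw-stream fixtures invert the
preprocessing: piecewise-constant 1 Hz four-site skin streams reproduce a
skin series exactly, and per-rest-window RRI tachograms built from LF
(0.10 Hz) and HF (0.30 Hz) sinusoids — a sinusoid of amplitude A carries
band power A²/2 — hit HRV targets to roughly ±0.3 on the log scale
(spectral-estimation bias; exactness is not attainable there).

What the generator does *not* emulate: between-participant
heterogeneity, non-Gaussian observation noise, circadian structure, and
cross-modality coupling.  Passing recovery and calibration tests
therefore demonstrates correctness of the machinery under the model's
own assumptions, not robustness to real-data misspecification.

## Problem sizes and test budget

The packaged experiments use the study-sized grids: T = 23 (HRV grid,
N = 6) for the convergence, recovery and forecast checks.  Convergence is
checked at the full 4 × (2000 + 2000) budget; the replication suites (20
replicates each) use scaled-down chains — 4 × 500 sampling draws for
parameter recovery, 2 short chains for the null-calibration and
forecast-calibration loops — sizes chosen so the whole suite runs on one
CPU in well under half an hour while keeping Monte-Carlo error small
relative to the asserted tolerances.

## Known limitations

* The Load/Env split is identified only softly, through smoothness
  (Load) versus periodicity (Env); with weak seasonal signal the damping
  factor h is poorly determined and Env can absorb slow variation.
* Credible-interval overlap is conservative as a difference criterion
  and carries no error-rate guarantee.
* One modality at a time: no joint multivariate model, no covariate
  effects (age, sex).
* The sampler's banded factorization assumes the seasonal length N is
  constant over the series, as it is on all protocol grids.
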