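# Methods

## The model

Relative PER2 bioluminescence (each animal's signal divided by its own mean,
so the natural scale is ~1) is described as the position `x` of a damped
harmonic oscillator around an equilibrium (the *intercept*):

```
x'' + γ x' + ω₀² x = F(t)
F(t)  = β · LMA(t) + A · sin(ω t + φ)
```

The oscillator is not self-sustained: without forcing, the rhythm decays at
the rate set by the damping constant γ (envelope `e^(-γt/2)`), with ω₀ the
natural angular frequency (`2π/ω₀` the intrinsic period) and ω₀² the string
constant. Two forces drive it:

* **sleep-wake force** `β·LMA(t)` — locomotor activity in counts per 6-min
  bin, used as the measurable proxy for time spent awake (hourly LMA and
  hourly time awake correlate above 0.9 in both real and synthetic data).
  β converts counts to h⁻².
* **peripheral circadian force** `A·sin(ωt+φ)` — a circadian drive
  independent of both the central pacemaker and the sleep-wake
  distribution, needed to explain the residual bioluminescence rhythm of
  behaviorally arrhythmic, SCN-lesioned animals. Its angular velocity ω is
  fixed at 2π/23.7 rad·h⁻¹, the free-running period estimated from those
  animals' baseline rhythm; A (h⁻²) and φ (rad) are free per experiment.

During enforced wakefulness LMA cannot be recorded; those bins are imputed
as 2.4 × the mean baseline activity, the empirically determined elevation of
activity under gentle-handling sleep deprivation.

### Numerics

The second-order ODE is integrated as the system `x1' = x2;
x2' = F − γx2 − ω₀²x1` with classic fixed-step fourth-order Runge-Kutta at
dt = 0.1 h. The 6-min LMA bins coincide with the integration steps, so the
forcing is held piecewise constant per step, including at RK4 half-steps —
no interpolation is introduced. Because the system is linear and the
forcing is constant within a step, one RK4 step is an affine map
`y⁺ = M y + s F`; the production path diagonalizes `M` and runs the
recursion through a C-level IIR filter (`scipy.signal.lfilter`), which is
bit-compatible with the explicit loop (asserted to 1e-12 in the tests) and
two orders of magnitude faster. Near critical damping (defective `M`) the
code falls back to the explicit loop. The zero-order hold of the forcing
delays the response by dt/2; this matters only for pointwise comparisons
against continuous-forcing closed forms, not for amplitudes.

Predictions for the 30-min observation grid average `x1` over each bin's
grid points and add the intercept (a point-sample mode is available; the
bin-mean is the default because observations are 30-min means).

Initial conditions: the lesioned-animal experiment starts from rest
`(x1, x2) = (0, 0)`. The 2hOnOff experiment starts from the state reached
after a 20-day warm-up on the baseline day's activity tiled backwards in
time, with the circadian force running continuously through the warm-up so
its phase is `φ` at time 0; at γ = 0.0155 h⁻¹ the warm-up transient retains
`e^(-γ·240) ≈ 2.4%` of its initial size, which the tests bound explicitly
rather than assuming exact convergence.

### Degenerate regimes

The circadian-force-only model (β = 0) admits the closed-form steady state
with amplitude `A/√((ω₀²−ω²)² + (γω)²)` and phase lag
`atan2(γω, ω₀²−ω²)`; the undamped resonance ω → ω₀, γ → 0 is rejected with
an explicit error rather than returning unbounded values. BIC is undefined
at RSS = 0 (a numerically perfect fit) and is flagged as −∞ instead of
raising inside a fit.

## Estimation

Free parameters (full model): γ, ω₀, β, intercept, A, φ. The objective is
the residual sum of squares over valid 30-min bins. Minimization uses
bound-constrained trust-region least squares (`scipy.optimize.least_squares`,
bounds γ ∈ [1e-4, 1] h⁻¹, ω₀ ∈ [2π/40, 2π/12] rad·h⁻¹, β ∈ [0, 1e-2],
intercept ∈ [0.5, 1.5], A ∈ [0, 0.1] h⁻², φ ∈ [0, 2π]) from multiple starts
— the first at configurable defaults, the rest drawn uniformly inside the
bounds from a seeded generator — because the phase parameter creates local
minima for single-start local optimizers. Every fit records its seed and
per-start RSS values.

Model variants drop one force: *wake-only* (A = φ = 0; 4 free parameters),
*circadian-only* (β = 0; 5 free parameters — the initial-condition transient
keeps γ and ω₀ identifiable), and the intercept-only *flat* model (solved
analytically). Comparison uses `BIC = n·ln(RSS/n) + k·ln(n)` with `k` the
number of optimized parameters plus one, and the approximate Bayes factor
`exp((BIC_flat − BIC_model)/2)`, oriented so that a model better than flat
has BF > 1 (BF > 100 read as decisive).

The two-experiment strategy mirrors the biology: γ, ω₀ and β are properties
of the tissue oscillator and are estimated once, on the lesioned-animal
experiment, then frozen; the circadian force (A, φ) and intercept are
re-estimated per experiment (stage-2 k = 4). The 6-h-SD experiment is
predicted with the stage-2 parameters without any refitting.

Uncertainty: parametric bootstrap. The residual sd is
`σ̂ = √(RSS/(n − n_optimized))`; 500 synthetic datasets (fitted prediction
plus i.i.d. Gaussian noise at σ̂) are each refit from the point estimate
(single start — the local-perturbation regime), and 95% CIs are the
empirical 2.5%/97.5% quantiles. Refits are aborted if more than 10% fail.
The calibration study in the acceptance tests (200 replicate experiments,
200 inner simulations each, sized to keep the suite within minutes) finds
pooled coverage ≈ 93% across the six parameters — the slight undercoverage
is the known price of bootstrapping from a point estimate.

## Signal preprocessing

Order fixed as detrend → normalize → bin. Detrending removes only the
least-squares slope and re-adds the pre-detrend mean, so the signal stays
positive and "relative to the overall mean" stays meaningful; normalization
then divides by the mean of valid bins. Re-binning averages valid
constituent bins and excludes an output bin when more than half of its
constituents are excluded (majority rule; chosen conservative). Bins are
labelled by start time, intervals half-open. Margins of 5 min before and
10 min after each sleep deprivation are masked (handling artefacts); bins
fully inside SDs can additionally be masked for cohorts removed from the
recorder during deprivations.

## Transition analysis

3-min blocks are *awake* when more than half their 45 four-second epochs are
wake (≥ 23); NREM and REM both count as sleep. A transition qualifies when
≥ 3 blocks of the initial state precede ≥ 5 blocks of the other state, and
extends over the full maximal runs on both sides; overlapping extents of
consecutive transitions are allowed, each transition being processed
independently. Each transition's trace is expressed as percent of the mean
of the last pre- and first post-transition block, aligned at the boundary,
averaged within and then across animals, and reported over the offsets to
which all animals contribute. Note one selection asymmetry: with the
asymmetric 3/5-block thresholds, two consecutive qualifying transitions can
share a direction (separated by a reversal too short to qualify), so
per-direction counts need not alternate.

## Synthetic data

The generator defines the study conditions for every test:

* **hypnogram** — alternating wake/sleep bouts with exponential durations;
  sleep bouts time-invariant (mean 12 min) and wake-bout means modulated
  sinusoidally at the circadian period with depth `m`
  (`m = 0.8` intact, `m = 0` lesioned/arrhythmic; modulation phase 2.78 rad,
  aligning wake propensity with the intact-animal circadian force). The
  long-run wake fraction targets 52% of recording time (≈ 42% NREM / 6% REM,
  REM placed as ~1-min bouts inside sleep at 12.5% of sleep). Bout-start
  phases are sampled size-biased under modulation, which would depress the
  realized wake fraction; a `1/(1 − m²/3)` factor on the wake-bout mean
  compensates (calibrated against the generator's own target). Exponential
  bout lengths are an assumption of convenience — real bout distributions
  are heavier-tailed — but the downstream analyses only require sustained
  bouts to occur at realistic rates, which they do (≈ 26 qualifying
  transitions per direction per animal over 2.5 days).
* **activity** — Poisson counts per 6-min bin with mean interpolating
  between 2 (sleep) and 150 (wake) counts by the bin's wake fraction; the
  implied baseline mean ≈ 76–81 counts/6-min puts the 2.4× SD imputation
  near 185, the order observed in vivo.
* **bioluminescence** — the oscillator integrated over the imputed activity
  trace, observed in 30-min bins with additive Gaussian noise
  (sd 0.02, the residual scale of the real group-average fits). With zero
  noise the chain is exactly invertible (asserted bit-level in the tests).

What the generator does *not* emulate: REM/NREM ultradian architecture
beyond bout alternation, sleep rebound after deprivation, state-dependent
observation noise, inter-animal parameter heterogeneity, and the
immediate-early-gene component of PER2 induction (fast transients at
transitions beyond what the oscillator produces). Passing tests therefore
demonstrate the correctness and calibration of the analysis chain under the
model's own assumptions, not the biological adequacy of the model for any
particular tissue.

## Problem sizes

Simulated recordings are 5–7 days per experiment (the in-vivo designs'
length): 336 thirty-minute observations for the repeated-SD experiment, 288
for the 2hOnOff. The parameter-recovery study uses 100 replicate
experiments; the bootstrap-calibration study 200 replicates with 200 inner
refits each (the method's production default is 500, used in the analysis
scripts). The phase sweep covers ±12 h in 25 steps with a full warm-up per
step.

## Known limitations

* The model is linear; amplitude responses to force scalings are exactly
  proportional, so saturation phenomena are out of reach by construction.
* Bootstrap CIs refit from the point estimate and mildly undercover
  (~93% pooled at nominal 95%); multi-start refits would close most of the
  gap at ~20× the cost.
* The circadian-only variant's γ and ω₀ are identified only through the
  initial transient and are weakly constrained when data begin near steady
  state.
* Group-level fitting (mean activity driving mean bioluminescence) ignores
  phase dispersion across animals; the phase-sweep machinery quantifies how
  strongly conclusions depend on that phase.
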