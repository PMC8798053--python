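# per2osc

Sleep-wake driven oscillator analysis of PER2 bioluminescence rhythms.

In peripheral tissues of the mouse, the clock protein PERIOD-2 (PER2, tracked
in vivo through a PER2::LUCIFERASE bioluminescence reporter) rises during
waking and falls during sleep, on top of its well-known circadian rhythm.
This package implements, end to end, the analysis chain needed to quantify
and model that interplay:

* **hypnogram analysis** — collapse 4-s wake/NREM/REM scorings to 3-min
  wake/sleep blocks (awake = more than 50%, i.e. ≥ 23 of 45 epochs), select
  sustained sleep-wake transitions (≥ 9 min of the initial state followed by
  ≥ 15 min of the other), and average transition-aligned bioluminescence as
  percent of the level at the transition;
* **signal preprocessing** — linear detrending, normalization to the
  per-animal mean, 30-min binning, masking of margins around enforced
  wakefulness;
* **the model** — a driven damped harmonic oscillator for relative PER2
  bioluminescence `x`:

  ```
  x'' + γ x' + ω₀² x = F(t),      F(t) = β·LMA(t) + A·sin(ωt + φ)
  ```

  driven by a sleep-wake force (β-scaled locomotor activity, LMA, the
  measurable proxy for time awake) and a circadian force that is independent
  of both the central pacemaker (SCN) and the sleep-wake distribution, with
  ω fixed to 2π/23.7 rad·h⁻¹ (the free-running period of the residual
  rhythm in SCN-lesioned animals). The system is integrated by fixed-step
  RK4 at 0.1 h with the forcing held piecewise constant per step;
* **inference** — box-constrained multi-start least squares on the residual
  sum of squares between the predicted oscillator position (plus intercept)
  and 30-min observations; model comparison by BIC
  (`n·ln(RSS/n) + k·ln(n)`, `k` = optimized parameters + 1) and approximate
  Bayes factors against an intercept-only flat model; parametric-bootstrap
  95% CIs (500 Monte-Carlo refits);
* **in-silico experiments** — counterfactual substitutions (arrhythmic
  sleep-wake input, alternative circadian-force magnitude), force-budget
  decomposition, and phase sweeps of the circadian force;
* **synthetic data** — a bout-based hypnogram generator with circadian
  modulation, Poisson locomotor activity tied to the wake fraction, and
  model-generated bioluminescence with known ground truth, so every stage is
  testable without any recordings.

## Worked example

The numbered scripts under `analysis/` run the whole chain on synthetic
experiments that emulate the in-vivo designs (an arrhythmic SCN-lesioned
animal under four daily 4-h sleep deprivations; an intact animal under two
days of alternating 2-h sleep deprivations and 2-h sleep opportunities; a
single 6-h sleep deprivation):

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_transitions.py
python analysis/04_fit_models.py
python analysis/05_counterfactuals.py
```

`04_fit_models.py` reprints, among other lines:

```
  scnx: gamma=0.0154 omega0=0.288 (intrinsic period 21.8 h) beta=6.39e-05
  onoff: A=0.00391 phi=2.76
scnx: best variant by BIC is full (BIC -2551.6, RSS 0.150); full-model BF vs flat 1.91e+241
sixsd predicted with onoff parameters (no refit): RSS 0.087 over 240 bins (rmse 0.0190)
```

Reading: the two-stage fit recovers the generating damping constant
(γ = 0.0155 h⁻¹), natural frequency (ω₀ = 0.288 rad·h⁻¹, a 21.8-h intrinsic
period) and wake-force coefficient from the lesioned-animal experiment, and
the intact-animal circadian force (A = 3.87e-3 h⁻², φ = 2.78 rad) from the
2hOnOff experiment; the model needs both forces (the full variant wins the
BIC comparison decisively in both experiments), and it predicts the held-out
6-h-SD experiment without refitting at close to the observation-noise floor
(rmse 0.019 vs noise sd 0.02). `05_counterfactuals.py` then shows that
swapping in an arrhythmic sleep-wake distribution or the lesioned animals'
weaker circadian force each flatten the predicted rhythm by roughly 20%, and
that a sufficiently large phase shift of the circadian force flips the
2hOnOff intervention from flattening to amplifying the PER2 rhythm.

A `per2osc` command-line interface wraps the same steps
(`simulate | preprocess | transitions | fit | counterfactual | report`);
`per2osc --help` lists them.

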