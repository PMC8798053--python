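"""Synthetic sleep-wake, activity and bioluminescence data with known truth.

The generator emulates the three streams of an in-vivo recording:

* a hypnogram of 4-s wake/NREM/REM epochs from a bout-based (semi-Markov)
  process — alternating wake and sleep bouts with exponential durations,
  the wake-bout mean modulated sinusoidally at the circadian period so
  that an intact animal shows a sinusoidal hourly-wake profile (lesioned
  animals are emulated with zero modulation depth);
* locomotor activity (LMA) as Poisson counts per 6-min bin whose rate
  tracks the wake fraction of the bin, making LMA a faithful proxy for
  wakefulness;
* bioluminescence generated by the driven damped harmonic oscillator with
  known parameters, observed in 30-min bins with additive Gaussian noise.

Bout durations are exponential by assumption (the field reports heavy-ish
tails, but no distribution is imposed by the analyses downstream); means
are chosen long enough that the >=9-min / >=15-min sustained-transition
criteria are frequently met, as they are in real mice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BinnedSignal, EpochSeries, NREM, REM, WAKE
from .oscillator import (DT, Forcing, OscillatorParams, OscState, Trajectory,
                         build_forcing, integrate_rk4, predict_observable,
                         warmup)
from .protocols import Protocol


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth configuration of a synthetic recording.

    Durations in hours, epoch length in seconds, bout means in minutes,
    LMA rates in expected counts per 6-min bin, ``noise_sd`` on the
    relative-bioluminescence scale.  ``bout_mean_wake=None`` derives the
    wake-bout mean from ``wake_fraction_mean`` and ``bout_mean_sleep`` so
    the long-run wake fraction hits its target.  ``circadian_modulation``
    (0..<1) scales the sinusoidal modulation of the wake-bout mean; 0 gives
    a behaviorally arrhythmic (SCN-lesioned-like) animal.
    """

    duration_h: float = 72.0
    epoch_len_s: float = 4.0
    circadian_period_h: float = 23.7
    wake_fraction_mean: float = 0.52
    rem_fraction: float = 0.125
    bout_mean_wake: float | None = None
    bout_mean_sleep: float = 12.0
    rem_bout_mean: float = 1.0
    circadian_modulation: float = 0.8
    modulation_phase: float = 2.78
    lma_rate_wake: float = 150.0
    lma_rate_sleep: float = 2.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.wake_fraction_mean < 1.0:
            raise ValueError("wake_fraction_mean must be in (0, 1)")
        if not 0.0 <= self.rem_fraction < 1.0:
            raise ValueError("rem_fraction must be in [0, 1)")
        if not 0.0 <= self.circadian_modulation < 1.0:
            raise ValueError("circadian_modulation must be in [0, 1)")
        for name in ("duration_h", "epoch_len_s", "circadian_period_h",
                     "bout_mean_sleep", "rem_bout_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bout_mean_wake is not None and self.bout_mean_wake <= 0:
            raise ValueError("bout_mean_wake must be strictly positive")
        for name in ("lma_rate_wake", "lma_rate_sleep", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def wake_bout_mean_min(self) -> float:
        """Wake-bout mean (min); derived from the target wake fraction."""
        if self.bout_mean_wake is not None:
            return self.bout_mean_wake
        f = self.wake_fraction_mean
        return self.bout_mean_sleep * f / (1.0 - f)

    @property
    def n_epochs(self) -> int:
        n = self.duration_h * 3600.0 / self.epoch_len_s
        k = round(n)
        if not math.isclose(n, k, rel_tol=1e-9):
            raise ValueError("duration is not a multiple of the epoch length")
        return k

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


def _fill_sleep_bout(rng: np.random.Generator, n_epochs: int,
                     cfg: SynthConfig, epoch_min: float) -> np.ndarray:
    """NREM/REM composition of one sleep bout (REM as short inner bouts)."""
    out = np.full(n_epochs, NREM, dtype="U1")
    r = cfg.rem_fraction
    if r == 0.0:
        return out
    nrem_mean = cfg.rem_bout_mean * (1.0 - r) / r
    i = 0
    in_rem = False
    while i < n_epochs:
        mean = cfg.rem_bout_mean if in_rem else nrem_mean
        k = max(1, round(rng.exponential(mean) / epoch_min))
        if in_rem:
            out[i:i + k] = REM
        i += k
        in_rem = not in_rem
    return out


def gen_hypnogram(config: SynthConfig) -> EpochSeries:
    """Simulate a scored hypnogram as alternating wake/sleep bouts.

    Wake-bout durations are exponential with a sinusoidally modulated mean
    ``mu_w(t) = mu_w * (1 + m*sin(2*pi*t/P + phase))``; sleep-bout durations
    are exponential with a time-invariant mean.  Identical config and seed
    give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_epochs
    epoch_min = config.epoch_len_s / 60.0
    states = np.empty(n, dtype="U1")
    mu_w = config.wake_bout_mean_min
    mu_s = config.bout_mean_sleep
    m = config.circadian_modulation
    w = 2.0 * math.pi / config.circadian_period_h

    # Bout cycles start more often in low-propensity phases (short wake
    # bouts), which size-biases the realized wake fraction downward under
    # modulation; the 1/(1 - m^2/3) factor compensates empirically so the
    # long-run fraction tracks wake_fraction_mean for any depth m.
    mu_w = mu_w / (1.0 - m * m / 3.0)

    awake = bool(rng.random() < config.wake_fraction_mean)
    i = 0
    while i < n:
        t_h = i * epoch_min / 60.0
        if awake:
            mean = mu_w * (1.0 + m * math.sin(w * t_h + config.modulation_phase))
            k = max(1, round(rng.exponential(mean) / epoch_min))
            states[i:i + k] = WAKE
        else:
            k = max(1, round(rng.exponential(mu_s) / epoch_min))
            k = min(k, n - i)
            states[i:i + k] = _fill_sleep_bout(rng, k, config, epoch_min)
        i += k
        awake = not awake
    return EpochSeries(start_time=0.0, epoch_len=config.epoch_len_s,
                       states=states)


def wake_fraction_per_bin(epochs: EpochSeries, bin_h: float = DT) -> BinnedSignal:
    """Fraction of each bin spent awake."""
    per = bin_h * 3600.0 / epochs.epoch_len
    k = round(per)
    if not math.isclose(per, k, rel_tol=1e-9) or epochs.n_epochs % k:
        raise ValueError("hypnogram must cover an integer number of bins")
    frac = epochs.is_wake().reshape(-1, k).mean(axis=1)
    return BinnedSignal(start_time=epochs.start_time, bin_width=bin_h,
                        values=frac, units="wake fraction")


def gen_lma(epochs: EpochSeries, config: SynthConfig) -> BinnedSignal:
    """Poisson locomotor-activity counts per 6-min bin.

    The Poisson mean interpolates between the sleeping and waking rates with
    the bin's wake fraction, which makes hourly LMA highly correlated with
    hourly time awake — the property that licenses LMA as the wake proxy in
    the oscillator's forcing.
    """
    rng = np.random.default_rng(config.seed + 1)
    frac = wake_fraction_per_bin(epochs, DT)
    mean = config.lma_rate_wake * frac.values \
        + config.lma_rate_sleep * (1.0 - frac.values)
    counts = rng.poisson(mean).astype(float)
    return BinnedSignal(start_time=epochs.start_time, bin_width=DT,
                        values=counts, units="counts/6min")


def apply_protocol(epochs: EpochSeries, lma: BinnedSignal, protocol: Protocol,
                   baseline_mean_lma: float) -> tuple[EpochSeries, BinnedSignal]:
    """Impose enforced wakefulness: states to wake, LMA to the imputed level.

    Epochs inside SD intervals are forced to wake; LMA bins inside SD
    intervals are set to ``2.4 * baseline_mean_lma``, matching how activity
    during sleep deprivation (when it cannot be measured) is estimated.
    """
    if protocol.is_empty:
        return epochs, lma
    end = epochs.start_time + epochs.duration_h
    for a, b in protocol.sd_intervals:
        if a < epochs.start_time - 1e-9 or b > end + 1e-9:
            raise ValueError("SD interval outside the hypnogram support")
    states = epochs.states.copy()
    states[protocol.in_sd(epochs.times_h)] = WAKE
    values = lma.values.copy()
    values[protocol.in_sd(lma.times_h)] = 2.4 * baseline_mean_lma
    return (EpochSeries(epochs.start_time, epochs.epoch_len, states),
            BinnedSignal(lma.start_time, lma.bin_width, values,
                         lma.valid.copy(), lma.units))


def gen_bioluminescence(lma: BinnedSignal, params: OscillatorParams,
                        config: SynthConfig, protocol: Protocol,
                        x0: OscState | None = None,
                        use_warmup: bool = False,
                        obs_width: float = 0.5
                        ) -> tuple[BinnedSignal, Trajectory]:
    """Observe the oscillator driven by the given activity trace.

    Integrates the model over the LMA support (SD bins already imputed by
    :func:`apply_protocol`, so no further imputation happens here), averages
    the position into ``obs_width``-h observation bins, adds the intercept
    and i.i.d. Gaussian noise of sd ``config.noise_sd``.  With
    ``use_warmup`` the initial state comes from 20 days of tiled baseline
    activity (first 24 h of the trace) instead of rest.

    Returns the noisy observations and the noise-free trajectory.
    """
    if protocol.sd_intervals and (
            protocol.sd_intervals[-1][1] > lma.end_time + 1e-9
            or protocol.sd_intervals[0][0] < lma.start_time - 1e-9):
        raise ValueError("protocol does not fit inside the activity trace")
    forcing = build_forcing(lma, params.beta, params.A, params.phi, params.omega)
    if use_warmup:
        day = lma.values[: round(24.0 / DT)]
        x0 = warmup(params, day)
    traj = integrate_rk4(params, forcing, x0)
    n_bins = int(lma.duration_h / obs_width)
    signal = predict_observable(traj, params.intercept, lma.start_time,
                                obs_width, n_bins)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed + 2)
        noisy = signal.values + rng.normal(0.0, config.noise_sd, signal.n_bins)
        signal = signal.with_values(noisy)
    return signal, traj


@dataclass(frozen=True)
class Experiment:
    """A complete synthetic recording with its ground truth."""

    config: SynthConfig
    params: OscillatorParams
    protocol: Protocol
    epochs: EpochSeries
    lma: BinnedSignal
    biolum: BinnedSignal
    trajectory: Trajectory
    baseline_mean_lma: float


def generate_experiment(config: SynthConfig, params: OscillatorParams,
                        protocol: Protocol,
                        use_warmup: bool = False) -> Experiment:
    """End-to-end synthesis: hypnogram -> LMA -> protocol -> bioluminescence.

    The baseline mean LMA used for sleep-deprivation imputation is the mean
    activity over the protocol's baseline window (the full trace when no
    baseline window is declared).
    """
    epochs = gen_hypnogram(config)
    lma = gen_lma(epochs, config)
    if protocol.baseline is not None:
        sl = lma.window_slice(*protocol.baseline)
        baseline_mean = float(lma.values[sl].mean())
    else:
        baseline_mean = float(lma.values.mean())
    epochs_sd, lma_sd = apply_protocol(epochs, lma, protocol, baseline_mean)
    biolum, traj = gen_bioluminescence(lma_sd, params, config, protocol,
                                       use_warmup=use_warmup)
    return Experiment(config=config, params=params, protocol=protocol,
                      epochs=epochs_sd, lma=lma_sd, biolum=biolum,
                      trajectory=traj, baseline_mean_lma=baseline_mean)
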