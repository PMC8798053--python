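"""In-silico experiments on a fitted oscillator: counterfactual substitutions,
amplitude-change quantification, and phase-perturbation sweeps.

A scenario re-simulates a fitted model after substituting one or more of its
inputs — the activity trace (e.g. replacing an intact animal's rhythmic
sleep-wake distribution by an arrhythmic one), the circadian-force amplitude
or phase, or the protocol — and reports how the amplitude of the predicted
bioluminescence rhythm changes.  "Amplitude" is always the amplitude of a
fixed-period (23.7-h) sinewave fit over the stated analysis window, so that
baseline and intervention windows are compared with the same estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import BinnedSignal
from .inference import FitResult, OscFitProblem
from .oscillator import (DT, Forcing, OscState, OscillatorParams, integrate_rk4,
                         peri_force, predict_observable, warmup)
from .protocols import Protocol
from .sinefit import fit_sine_signal

#: Period (hours) of the fixed-period amplitude estimator.
AMPLITUDE_PERIOD_H = 23.7


@dataclass(frozen=True)
class Scenario:
    """Input substitutions applied to a fitted model before re-simulation.

    Any of the fields may be left ``None`` to keep the fitted value; at
    least one must be set (``allow_identity`` in :func:`run_scenario`
    relaxes this for control runs).
    """

    name: str = "scenario"
    lma_values: np.ndarray | None = None
    A: float | None = None
    phi: float | None = None
    phi_shift_h: float | None = None
    protocol: Protocol | None = None

    def is_identity(self) -> bool:
        return (self.lma_values is None and self.A is None
                and self.phi is None and self.phi_shift_h is None
                and self.protocol is None)


@dataclass(frozen=True)
class ScenarioReport:
    """Amplitudes and relative change of a scenario against its base run."""

    name: str
    amplitude_base: float
    amplitude_alt: float
    percent_change: float
    window: tuple[float, float]
    prediction: BinnedSignal


def simulate_fit(params: OscillatorParams, lma_values: np.ndarray, t0: float,
                 use_warmup: bool, x0: OscState | None = None,
                 obs_width: float = 0.5) -> BinnedSignal:
    """Noise-free model prediction for a given activity trace."""
    n_steps = lma_values.size
    t = t0 + DT * np.arange(n_steps)
    forcing = Forcing(t0=t0, dt=DT, f_wake=params.beta * lma_values,
                      f_peri=peri_force(t, params.A, params.phi, params.omega))
    if use_warmup:
        day = lma_values[: round(24.0 / DT)]
        x0 = warmup(params, day)
    traj = integrate_rk4(params, forcing, x0 or OscState())
    n_bins = int(n_steps * DT / obs_width)
    return predict_observable(traj, params.intercept, t0, obs_width, n_bins)


def amplitude_in_window(pred: BinnedSignal, window: tuple[float, float],
                        period: float = AMPLITUDE_PERIOD_H) -> float:
    """Fixed-period sinewave-fit amplitude of a prediction over a window."""
    return fit_sine_signal(pred, window=window, period=period).a


def amplitude_change(pred_base: BinnedSignal, pred_alt: BinnedSignal,
                     window: tuple[float, float],
                     period: float = AMPLITUDE_PERIOD_H) -> float:
    """Percent amplitude reduction of ``pred_alt`` relative to ``pred_base``.

    ``100 * (1 - a_alt / a_base)``; positive values mean the alternative
    run is flatter.
    """
    a_base = amplitude_in_window(pred_base, window, period)
    a_alt = amplitude_in_window(pred_alt, window, period)
    if a_base == 0:
        raise ZeroDivisionError("base amplitude is zero; change undefined")
    return 100.0 * (1.0 - a_alt / a_base)


def _apply_scenario_params(params: OscillatorParams,
                           scenario: Scenario) -> OscillatorParams:
    kw: dict[str, float] = {}
    if scenario.A is not None:
        kw["A"] = scenario.A
    if scenario.phi is not None:
        kw["phi"] = scenario.phi
    if scenario.phi_shift_h is not None:
        base_phi = kw.get("phi", params.phi)
        # A phase *advance* of dt hours moves the sinewave earlier in time:
        # sin(w(t + dt) + phi) = sin(wt + (phi + w*dt)).
        kw["phi"] = (base_phi + params.omega * scenario.phi_shift_h) % (2 * math.pi)
    return params.replace(**kw) if kw else params


def run_scenario(fit: FitResult, problem: OscFitProblem, scenario: Scenario,
                 window: tuple[float, float] | None = None,
                 base_window: tuple[float, float] | None = None,
                 allow_identity: bool = False,
                 base_on_alt: bool = False) -> ScenarioReport:
    """Re-simulate a fitted model with substituted inputs and compare
    amplitudes.

    By default the base amplitude is measured on the *unmodified* fitted
    prediction over ``base_window`` (default: ``window``) — the natural
    comparison for input substitutions ("how much rhythm is lost without
    this ingredient").  With ``base_on_alt`` both amplitudes come from the
    substituted run, comparing its intervention window against its own
    baseline — the comparison used by the phase sweep.  The alternative
    amplitude is always taken on the substituted run over ``window``
    (default: the problem's intervention window, falling back to the full
    support).  The fit itself is never modified.
    """
    if scenario.is_identity() and not allow_identity:
        raise ValueError("scenario substitutes nothing; pass allow_identity=True "
                         "for an explicit control run")
    params = _apply_scenario_params(fit.params, scenario)
    lma = scenario.lma_values if scenario.lma_values is not None \
        else problem.lma_values
    if scenario.protocol is not None:
        from .oscillator import impute_sd_lma as _imp
        from .core import BinnedSignal as _BS
        if problem.baseline_mean_lma is None:
            raise ValueError("protocol substitution needs a baseline mean LMA")
        lma = _imp(_BS(problem.t0, DT, lma), scenario.protocol,
                   problem.baseline_mean_lma)
    if lma.size != problem.lma_values.size:
        raise ValueError("substituted activity trace has the wrong length")

    if window is None:
        if problem.protocol.intervention is not None:
            window = problem.protocol.intervention
        else:
            window = (problem.t0, problem.t0 + problem.lma_values.size * DT)
    base_window = base_window or window

    pred_alt = simulate_fit(params, lma, problem.t0, problem.use_warmup,
                            problem.x0)
    if base_on_alt:
        a_base = amplitude_in_window(pred_alt, base_window)
    else:
        pred_base = simulate_fit(fit.params, problem.lma_values, problem.t0,
                                 problem.use_warmup, problem.x0)
        a_base = amplitude_in_window(pred_base, base_window)
    a_alt = amplitude_in_window(pred_alt, window)
    pct = 100.0 * (1.0 - a_alt / a_base)
    return ScenarioReport(name=scenario.name, amplitude_base=a_base,
                          amplitude_alt=a_alt, percent_change=pct,
                          window=window, prediction=pred_alt)


def phase_sweep(fit: FitResult, problem: OscFitProblem,
                shifts_h: np.ndarray,
                window: tuple[float, float] | None = None,
                base_window: tuple[float, float] | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude change as a function of a phase shift of the circadian force.

    For each shift (hours; positive = phase advance) the circadian force's
    phase is advanced by ``omega * shift``, the warm-up re-run (the warm-up
    state depends on the phase), the experiment re-simulated, and the
    percent change of the shifted run's intervention-window amplitude
    relative to *its own* baseline-window amplitude recorded — positive
    values mean the intervention flattens the rhythm at that phase.
    Returns ``(shifts_h, percent_change)``.
    """
    shifts_h = np.asarray(shifts_h, dtype=float)
    if np.any(np.abs(shifts_h) > 12.0 + 1e-9):
        raise ValueError("phase shifts are restricted to +/- 12 h")
    changes = np.empty(shifts_h.size)
    for i, dt_h in enumerate(shifts_h):
        rep = run_scenario(fit, problem,
                           Scenario(name=f"phase_shift_{dt_h:+.2f}h",
                                    phi_shift_h=float(dt_h)),
                           window=window, base_window=base_window,
                           allow_identity=True, base_on_alt=True)
        changes[i] = rep.percent_change
    return shifts_h, changes


def zero_crossing_shift(shifts_h: np.ndarray, changes: np.ndarray) -> float | None:
    """First sign change of the amplitude-change curve (linear interpolation)."""
    s = np.sign(changes)
    idx = np.flatnonzero(np.diff(s) != 0)
    if idx.size == 0:
        return None
    i = int(idx[0])
    x0, x1 = shifts_h[i], shifts_h[i + 1]
    y0, y1 = changes[i], changes[i + 1]
    if y1 == y0:
        return float(x0)
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))
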