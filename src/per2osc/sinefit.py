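"""Sinewave fitting: amplitude, phase and period of rhythmic signals.

The estimator throughout the analysis is nonlinear least squares of

    y(t) = Y0 + a * sin(2*pi/b * t + c)

with the period ``b`` either free (box-constrained to the circadian range
18-30 h) or pinned.  Amplitude is reported non-negative; a negative fitted
``a`` is absorbed into the phase by ``c <- c + pi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import BinnedSignal

#: Box constraints for free-period fits, hours (circadian range).
PERIOD_BOUNDS = (18.0, 30.0)
TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SineFit:
    """Fitted sinewave ``Y0 + a*sin(2*pi/b*t + c)``.

    ``a >= 0``; ``c`` wrapped to ``[0, 2*pi)``; ``rss`` is the residual sum
    of squares at the optimum.
    """

    Y0: float
    a: float
    b: float
    c: float
    rss: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.Y0 + self.a * np.sin(TWO_PI / self.b * np.asarray(t) + self.c)

    @property
    def peak_time_h(self) -> float:
        return peak_time(self.c, self.b)


def peak_time(c: float, period: float) -> float:
    """First nonnegative time at which ``sin(2*pi/period*t + c)`` is maximal.

    The sine peaks when its argument is ``pi/2 (mod 2*pi)``, i.e. at
    ``t = ((pi/2 - c) mod 2*pi) * period / (2*pi)``.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    return ((math.pi / 2.0 - c) % TWO_PI) * period / TWO_PI


def _initial_phase(t: np.ndarray, y: np.ndarray, period: float) -> float:
    """Phase of the first harmonic at the trial period (DFT projection)."""
    w = TWO_PI / period
    s = np.sum((y - y.mean()) * np.sin(w * t))
    c = np.sum((y - y.mean()) * np.cos(w * t))
    # y ~ a*sin(wt + phi) => projections (s, c) ~ (a*cos(phi), a*sin(phi))
    return math.atan2(c, s) % TWO_PI


def fit_sine(t: np.ndarray, y: np.ndarray, period: float | None = None,
             period_bounds: tuple[float, float] = PERIOD_BOUNDS,
             init_period: float = 24.0) -> SineFit:
    """Least-squares sinewave fit.

    Parameters
    ----------
    t, y
        Sample times (hours) and values; NaNs are dropped.
    period
        If given, the period is fixed at this value; otherwise it is a free
        parameter constrained to ``period_bounds``.
    init_period
        Starting period for free-period fits.

    Raises
    ------
    ValueError
        Fewer than 8 valid points, a span shorter than one period, or a
        constant signal.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 8:
        raise ValueError("need at least 8 valid points")
    p_ref = period if period is not None else init_period
    if t.max() - t.min() < p_ref:
        raise ValueError("samples must span at least one period")
    if np.ptp(y) == 0:
        raise ValueError("cannot fit a sinewave to a constant signal")

    y0_init = float(y.mean())
    a_init = float(math.sqrt(2.0) * y.std())

    if period is not None:
        c_init = _initial_phase(t, y, period)

        def resid(p):
            Y0, a, c = p
            return Y0 + a * np.sin(TWO_PI / period * t + c) - y

        sol = least_squares(resid, [y0_init, a_init, c_init], method="lm")
        Y0, a, c = sol.x
        b = period
    else:
        c_init = _initial_phase(t, y, init_period)

        def resid(p):
            Y0, a, b, c = p
            return Y0 + a * np.sin(TWO_PI / b * t + c) - y

        lo = [-np.inf, 0.0, period_bounds[0], -TWO_PI]
        hi = [np.inf, np.inf, period_bounds[1], 2 * TWO_PI]
        sol = least_squares(resid, [y0_init, abs(a_init), init_period, c_init],
                            bounds=(lo, hi))
        Y0, a, b, c = sol.x
    if a < 0:
        a, c = -a, c + math.pi
    return SineFit(Y0=float(Y0), a=float(a), b=float(b), c=float(c % TWO_PI),
                   rss=float(np.sum(sol.fun**2)))


def fit_sine_signal(signal: BinnedSignal, window: tuple[float, float] | None = None,
                    period: float | None = None, **kw) -> SineFit:
    """Sinewave fit over the valid bins of a signal, optionally windowed."""
    t = signal.mid_times_h
    y = signal.values.copy()
    y[~signal.valid] = np.nan
    if window is not None:
        sl = signal.window_slice(*window)
        t, y = t[sl], y[sl]
    return fit_sine(t, y, period=period, **kw)


def estimate_free_running_period(biolums: list[BinnedSignal],
                                 window: tuple[float, float] | None = None
                                 ) -> tuple[np.ndarray, float, float]:
    """Free-period sinewave fit per animal over a baseline window.

    Returns the per-animal periods plus their mean and SD (SD is 0 for a
    single animal).  Used to estimate the free-running period of the residual
    bioluminescence rhythm in arrhythmic (SCN-lesioned) animals, which in
    turn pins the circadian-force period of the oscillator model.
    """
    periods = np.array([
        fit_sine_signal(s, window=window, period=None).b for s in biolums
    ])
    return periods, float(periods.mean()), float(periods.std(ddof=1) if periods.size > 1 else 0.0)
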