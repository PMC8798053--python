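"""Experimental protocols: enforced-wakefulness schedules and analysis windows.

Three interventions are supported, mirroring the in-vivo designs this package
analyses:

* ``six_hour_sd`` — a single 6-h sleep deprivation (SD) after a baseline.
* ``repeated_4h_sd`` — four 4-h SDs repeated at 24-h intervals (used to
  impose a daily sleep-wake rhythm on behaviorally arrhythmic,
  SCN-lesioned mice).
* ``two_h_on_off`` — two days of 12 alternating 2-h SDs, each followed by a
  2-h sleep opportunity window (SOW); flattens the circadian sleep-wake
  distribution in intact mice.

A :class:`Protocol` carries the SD intervals plus the phase boundaries
(baseline / intervention / recovery) used for windowed amplitude analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Interval = tuple[float, float]


@dataclass(frozen=True)
class Protocol:
    """Enforced-wakefulness schedule within a recording.

    Attributes
    ----------
    name
        One of ``{"six_hour_sd", "repeated_4h_sd", "two_h_on_off", "none"}``.
    sd_intervals
        Sorted, non-overlapping ``(start_h, end_h)`` half-open intervals of
        enforced wakefulness.
    baseline, intervention, recovery
        ``(start_h, end_h)`` analysis windows; ``None`` when absent.
    """

    name: str = "none"
    sd_intervals: tuple[Interval, ...] = ()
    baseline: Interval | None = None
    intervention: Interval | None = None
    recovery: Interval | None = None

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.sd_intervals)
        for a, b in ivs:
            if b <= a:
                raise ValueError(f"empty or inverted SD interval ({a}, {b})")
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("SD intervals must be sorted and non-overlapping")
        object.__setattr__(self, "sd_intervals", ivs)

    @property
    def is_empty(self) -> bool:
        return len(self.sd_intervals) == 0

    def in_sd(self, t: np.ndarray | float) -> np.ndarray:
        """Boolean mask: times inside any SD interval (half-open)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for a, b in self.sd_intervals:
            out |= (t >= a) & (t < b)
        return out

    def sd_overlap_fraction(self, t0: np.ndarray, width: float) -> np.ndarray:
        """Fraction of each bin ``[t0, t0+width)`` covered by SD intervals."""
        t0 = np.asarray(t0, dtype=float)
        cover = np.zeros(t0.shape, dtype=float)
        for a, b in self.sd_intervals:
            lo = np.maximum(t0, a)
            hi = np.minimum(t0 + width, b)
            cover += np.clip(hi - lo, 0.0, None)
        return cover / width


def six_hour_sd(baseline_h: float = 48.0, sd_len_h: float = 6.0,
                recovery_h: float = 48.0) -> Protocol:
    """Single SD of ``sd_len_h`` hours starting right after the baseline."""
    t0 = baseline_h
    return Protocol(
        name="six_hour_sd",
        sd_intervals=((t0, t0 + sd_len_h),),
        baseline=(0.0, baseline_h),
        intervention=(t0, t0 + sd_len_h),
        recovery=(t0 + sd_len_h, t0 + sd_len_h + recovery_h),
    )


def repeated_4h_sd(baseline_h: float = 48.0, n_days: int = 4,
                   sd_len_h: float = 4.0, recovery_h: float = 24.0) -> Protocol:
    """``n_days`` daily SDs of ``sd_len_h`` hours at 24-h intervals."""
    ivs = tuple((baseline_h + 24.0 * d, baseline_h + 24.0 * d + sd_len_h)
                for d in range(n_days))
    end = baseline_h + 24.0 * (n_days - 1) + sd_len_h
    return Protocol(
        name="repeated_4h_sd",
        sd_intervals=ivs,
        baseline=(0.0, baseline_h),
        intervention=(baseline_h, end),
        recovery=(baseline_h + 24.0 * n_days, baseline_h + 24.0 * n_days + recovery_h),
    )


def two_h_on_off(baseline_h: float = 48.0, recovery_h: float = 48.0) -> Protocol:
    """Two days of 12 alternating 2-h SDs each followed by a 2-h SOW."""
    ivs = tuple((baseline_h + 4.0 * k, baseline_h + 4.0 * k + 2.0)
                for k in range(12))
    end = baseline_h + 48.0
    return Protocol(
        name="two_h_on_off",
        sd_intervals=ivs,
        baseline=(0.0, baseline_h),
        intervention=(baseline_h, end),
        recovery=(end, end + recovery_h),
    )


def no_protocol(duration_h: float) -> Protocol:
    """Undisturbed recording; the whole span is baseline."""
    return Protocol(name="none", baseline=(0.0, duration_h))


_BUILDERS = {
    "six_hour_sd": six_hour_sd,
    "repeated_4h_sd": repeated_4h_sd,
    "two_h_on_off": two_h_on_off,
}


def make_protocol(name: str, **kwargs) -> Protocol:
    """Build a named protocol; ``none`` requires ``duration_h``."""
    if name == "none":
        return no_protocol(kwargs.get("duration_h", 48.0))
    try:
        return _BUILDERS[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown protocol {name!r}") from None
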