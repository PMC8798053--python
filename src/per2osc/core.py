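"""Core time-series containers shared across the package.

Two containers cover everything the analysis touches:

* :class:`EpochSeries` — a scored hypnogram, i.e. a dense sequence of
  4-s sleep-wake state labels (wake / NREM sleep / REM sleep).
* :class:`BinnedSignal` — a regularly binned numeric signal (bioluminescence,
  locomotor activity counts, minutes awake, ...) with a per-bin validity mask
  so that excluded stretches survive every downstream operation.

All times are decimal hours from recording start.  Bins are labelled by
their start time and cover the half-open interval ``[t, t + bin_width)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: State codes used throughout: wake, NREM sleep, REM sleep.
WAKE, NREM, REM = "W", "N", "R"
STATES = (WAKE, NREM, REM)


@dataclass(frozen=True)
class EpochSeries:
    """Per-animal sequence of scored sleep-wake epochs.

    Parameters
    ----------
    start_time
        Recording start, hours.
    epoch_len
        Epoch duration in **seconds** (scoring resolution, default 4 s).
    states
        Array of single-character codes drawn from ``{"W", "N", "R"}``.
    """

    start_time: float
    epoch_len: float
    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype="U1")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        if states.size == 0:
            raise ValueError("states must be non-empty")
        bad = ~np.isin(states, STATES)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"unknown state code {states[idx]!r} at epoch {idx}"
            )
        object.__setattr__(self, "states", states)

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_h(self) -> float:
        """Total covered duration in hours."""
        return self.n_epochs * self.epoch_len / 3600.0

    @property
    def times_h(self) -> np.ndarray:
        """Epoch start times in hours."""
        return self.start_time + np.arange(self.n_epochs) * (self.epoch_len / 3600.0)

    def is_wake(self) -> np.ndarray:
        """Boolean array, True where the animal is awake."""
        return self.states == WAKE


@dataclass(frozen=True)
class BinnedSignal:
    """Regularly binned numeric signal with a validity mask.

    ``values[i]`` covers ``[start_time + i*bin_width, start_time + (i+1)*bin_width)``
    hours.  ``valid[i]`` is False for bins excluded from analysis (recording
    gaps, margins around enforced-wakefulness intervals, ...); invalid bins
    keep their stored value so that masking is reversible and composable.
    """

    start_time: float
    bin_width: float
    values: np.ndarray
    valid: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        valid = self.valid
        if valid is None:
            valid = np.ones(values.shape, dtype=bool)
        else:
            valid = np.asarray(valid, dtype=bool)
            if valid.shape != values.shape:
                raise ValueError("values and valid must have the same length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)

    @property
    def n_bins(self) -> int:
        return int(self.values.size)

    @property
    def duration_h(self) -> float:
        return self.n_bins * self.bin_width

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_h

    @property
    def times_h(self) -> np.ndarray:
        """Bin start times in hours."""
        return self.start_time + np.arange(self.n_bins) * self.bin_width

    @property
    def mid_times_h(self) -> np.ndarray:
        """Bin midpoint times in hours."""
        return self.times_h + 0.5 * self.bin_width

    def with_values(self, values: np.ndarray) -> "BinnedSignal":
        return replace(self, values=np.asarray(values, dtype=float))

    def with_valid(self, valid: np.ndarray) -> "BinnedSignal":
        return replace(self, valid=np.asarray(valid, dtype=bool))

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def same_grid(self, other: "BinnedSignal", rtol: float = 1e-9) -> bool:
        return (
            self.n_bins == other.n_bins
            and np.isclose(self.start_time, other.start_time, rtol=0, atol=1e-9)
            and np.isclose(self.bin_width, other.bin_width, rtol=rtol)
        )

    def window_slice(self, t0: float, t1: float) -> slice:
        """Index slice of bins fully inside the half-open window ``[t0, t1)``."""
        i0 = int(np.ceil((t0 - self.start_time) / self.bin_width - 1e-9))
        i1 = int(np.floor((t1 - self.start_time) / self.bin_width + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_bins)
        return slice(i0, max(i0, i1))


def require_same_grid(a: BinnedSignal, b: BinnedSignal) -> None:
    if not a.same_grid(b):
        raise ValueError("signals are not on the same time grid")
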