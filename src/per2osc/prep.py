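"""Preprocessing of raw per-animal series: detrend, normalize, bin, mask.

The pipeline order is fixed: linear detrending (drift removal, offset by the
pre-detrend mean so values stay positive), then normalization to the
per-animal mean, then re-binning.  Bioluminescence is expressed relative to
the overall mean per mouse to absorb inter-individual differences in
absolute signal (pump placement, substrate delivery).
"""

from __future__ import annotations

import numpy as np

from .core import BinnedSignal, require_same_grid
from .protocols import Protocol


def detrend_linear(signal: BinnedSignal, keep_offset: bool = True) -> BinnedSignal:
    """Remove the least-squares straight line fitted over valid bins.

    With ``keep_offset`` (default) the pre-detrend mean of the valid bins is
    added back so that the detrended signal remains positive and a subsequent
    mean-normalization stays meaningful; only the slope is removed either way.
    Excluded bins are detrended too (the line is defined everywhere) but stay
    excluded.
    """
    if int(signal.valid.sum()) < 2:
        raise ValueError("detrending needs at least 2 valid bins")
    t = signal.mid_times_h
    y = signal.values
    coef = np.polynomial.polynomial.polyfit(t[signal.valid], y[signal.valid], 1)
    line = coef[0] + coef[1] * t
    out = y - line
    if keep_offset:
        out = out + float(np.mean(y[signal.valid]))
    return signal.with_values(out)


def normalize_to_mean(signal: BinnedSignal) -> BinnedSignal:
    """Express every value relative to the mean of the valid bins."""
    m = float(np.mean(signal.valid_values()))
    if abs(m) < 1e-300:
        raise ValueError(
            "cannot normalize a zero-mean signal; normalize before removing "
            "the offset, or detrend with keep_offset=True"
        )
    return signal.with_values(signal.values / m)


def bin_average(signal: BinnedSignal, new_width: float) -> BinnedSignal:
    """Re-bin to a coarser grid by averaging valid constituent bins.

    ``new_width`` must be an integer multiple of the current width.  An
    output bin is excluded when more than half of its constituent bins are
    excluded; otherwise its value is the mean of the valid constituents.
    """
    ratio = new_width / signal.bin_width
    k = round(ratio)
    if k < 1 or not np.isclose(ratio, k, rtol=1e-9):
        raise ValueError(
            f"new width {new_width} h is not an integer multiple of "
            f"{signal.bin_width} h"
        )
    n_out = signal.n_bins // k
    vals = signal.values[: n_out * k].reshape(n_out, k)
    ok = signal.valid[: n_out * k].reshape(n_out, k)
    n_ok = ok.sum(axis=1)
    out_valid = n_ok * 2 > k  # >50% of constituents must be valid
    with np.errstate(invalid="ignore"):
        out_vals = np.where(n_ok > 0,
                            np.where(ok, vals, 0.0).sum(axis=1) / np.maximum(n_ok, 1),
                            np.nan)
    return BinnedSignal(start_time=signal.start_time, bin_width=new_width,
                        values=out_vals, valid=out_valid, units=signal.units)


def exclude_sd_margins(signal: BinnedSignal, protocol: Protocol,
                       pre_min: float = 5.0, post_min: float = 10.0,
                       exclude_during_sd: bool = False) -> BinnedSignal:
    """Flag bins around (and optionally during) sleep deprivations as excluded.

    Bins intersecting ``[SD_start - pre_min, SD_start)`` or
    ``(SD_end, SD_end + post_min]`` (minutes) are excluded: signal around the
    handling of the animal is unreliable.  ``exclude_during_sd`` additionally
    drops bins fully inside SD intervals, for cohorts removed from the
    recorder during enforced wakefulness.
    """
    if protocol.is_empty:
        return signal
    t0 = signal.times_h
    t1 = t0 + signal.bin_width
    drop = np.zeros(signal.n_bins, dtype=bool)
    pre_h, post_h = pre_min / 60.0, post_min / 60.0
    for a, b in protocol.sd_intervals:
        drop |= (t1 > a - pre_h) & (t0 < a)          # pre-SD margin
        drop |= (t1 > b) & (t0 < b + post_h + 1e-12)  # post-SD margin
        if exclude_during_sd:
            drop |= (t0 >= a - 1e-12) & (t1 <= b + 1e-12)
    return signal.with_valid(signal.valid & ~drop)


def average_across_animals(signals: list[BinnedSignal]) -> BinnedSignal:
    """Per-bin mean over animals, using each animal's valid bins only.

    A bin is excluded in the output only when no animal has it valid.
    """
    if not signals:
        raise ValueError("need at least one signal")
    first = signals[0]
    for s in signals[1:]:
        require_same_grid(first, s)
    vals = np.stack([s.values for s in signals])
    ok = np.stack([s.valid for s in signals])
    n_ok = ok.sum(axis=0)
    out_vals = np.where(ok, vals, 0.0).sum(axis=0) / np.maximum(n_ok, 1)
    out_vals = np.where(n_ok > 0, out_vals, np.nan)
    return BinnedSignal(start_time=first.start_time, bin_width=first.bin_width,
                        values=out_vals, valid=n_ok > 0, units=first.units)


def preprocess_bioluminescence(raw: BinnedSignal, protocol: Protocol,
                               obs_width: float = 0.5,
                               exclude_during_sd: bool = False) -> BinnedSignal:
    """Standard pipeline: detrend -> normalize -> mask SD margins -> 30-min bins."""
    s = detrend_linear(raw)
    s = normalize_to_mean(s)
    s = exclude_sd_margins(s, protocol, exclude_during_sd=exclude_during_sd)
    if not np.isclose(s.bin_width, obs_width, rtol=1e-9):
        s = bin_average(s, obs_width)
    return s
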