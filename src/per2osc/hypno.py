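"""Hypnogram analysis: 3-min wake/sleep classification, sustained
state-transition detection, and transition-aligned bioluminescence traces.

Changes in PER2 are slow relative to the 4-s scoring resolution, so epochs
are first collapsed to 3-min blocks (45 epochs): a block is *awake* when the
animal was awake more than half of it, i.e. 23 or more epochs; NREM and REM
sleep both count as sleep.  A transition qualifies when at least 9 min
(3 blocks) of the initial state are followed by at least 15 min (5 blocks)
of the other state; each transition is then extended forward and backward
for as long as the state does not change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinnedSignal, EpochSeries, NREM, REM, WAKE

#: Blocks are 3 min; 45 four-second epochs per block.
BLOCK_MIN = 3.0
EPOCHS_PER_BLOCK = 45
#: Strict-majority wake threshold: smallest count exceeding 50% of 45.
WAKE_EPOCH_THRESHOLD = EPOCHS_PER_BLOCK // 2 + 1


@dataclass(frozen=True)
class Transition:
    """One qualifying state transition in units of 3-min blocks.

    ``index`` is the first block of the new state; time 0 of the transition
    is the boundary between blocks ``index - 1`` and ``index``.
    ``pre_blocks``/``post_blocks`` are the full maximal run lengths.
    """

    index: int
    direction: str  # "sleep_to_wake" | "wake_to_sleep"
    pre_blocks: int
    post_blocks: int

    @property
    def pre_extent_min(self) -> float:
        return self.pre_blocks * BLOCK_MIN

    @property
    def post_extent_min(self) -> float:
        return self.post_blocks * BLOCK_MIN


@dataclass(frozen=True)
class TransitionSet:
    """All qualifying transitions of a block sequence, with its time origin."""

    start_time: float
    transitions: tuple[Transition, ...]

    def by_direction(self, direction: str) -> tuple[Transition, ...]:
        return tuple(t for t in self.transitions if t.direction == direction)

    def times_h(self) -> np.ndarray:
        return self.start_time + np.array(
            [t.index * BLOCK_MIN / 60.0 for t in self.transitions]
        )


def classify_3min_intervals(epochs: EpochSeries) -> np.ndarray:
    """Collapse 4-s epochs to a per-3-min wake(True)/sleep(False) sequence."""
    if not np.isclose(epochs.epoch_len, 4.0, rtol=1e-9):
        raise ValueError("classification requires 4-s epochs")
    n_blocks = epochs.n_epochs // EPOCHS_PER_BLOCK
    if n_blocks * EPOCHS_PER_BLOCK != epochs.n_epochs:
        raise ValueError(
            f"epoch count {epochs.n_epochs} is not a multiple of "
            f"{EPOCHS_PER_BLOCK} (3-min blocks)"
        )
    wake = epochs.is_wake()[: n_blocks * EPOCHS_PER_BLOCK]
    counts = wake.reshape(n_blocks, EPOCHS_PER_BLOCK).sum(axis=1)
    return counts >= WAKE_EPOCH_THRESHOLD


def select_transitions(blocks: np.ndarray, min_pre: int = 3, min_post: int = 5,
                       start_time: float = 0.0) -> TransitionSet:
    """Find all sustained transitions in a wake/sleep block sequence.

    A change at block ``i`` qualifies when the maximal run ending at
    ``i - 1`` has length >= ``min_pre`` and the maximal run starting at ``i``
    has length >= ``min_post``.  Extents are the full maximal runs, so
    consecutive transitions may share blocks.
    """
    blocks = np.asarray(blocks, dtype=bool)
    n = blocks.size
    # run_back[i]: length of the maximal constant run ending at i
    # run_fwd[i]: length of the maximal constant run starting at i
    run_back = np.ones(n, dtype=int)
    run_fwd = np.ones(n, dtype=int)
    for i in range(1, n):
        if blocks[i] == blocks[i - 1]:
            run_back[i] = run_back[i - 1] + 1
    for i in range(n - 2, -1, -1):
        if blocks[i] == blocks[i + 1]:
            run_fwd[i] = run_fwd[i + 1] + 1
    found = []
    for i in range(1, n):
        if blocks[i] != blocks[i - 1] and run_back[i - 1] >= min_pre \
                and run_fwd[i] >= min_post:
            direction = "sleep_to_wake" if blocks[i] else "wake_to_sleep"
            found.append(Transition(index=i, direction=direction,
                                    pre_blocks=int(run_back[i - 1]),
                                    post_blocks=int(run_fwd[i])))
    return TransitionSet(start_time=start_time, transitions=tuple(found))


def align_transition(biolum: BinnedSignal, tr: Transition,
                     start_time: float) -> tuple[np.ndarray, np.ndarray] | None:
    """Percent-of-reference trace of one transition on the 3-min grid.

    The reference level is the mean of the last pre-transition 3-min value
    and the first post-transition value; every block in the transition's
    extent is expressed as ``100 * value / reference``.  Returns
    ``(offsets_in_blocks, percent)`` with offset 0 the first post block, or
    ``None`` when the extent leaves the signal support or touches an
    excluded bin at the reference.
    """
    if not np.isclose(biolum.bin_width * 60.0, BLOCK_MIN, rtol=1e-9):
        raise ValueError("bioluminescence must be on the 3-min grid")
    t_boundary = start_time + tr.index * BLOCK_MIN / 60.0
    i = round((t_boundary - biolum.start_time) / biolum.bin_width)
    lo, hi = i - tr.pre_blocks, i + tr.post_blocks
    if lo < 0 or hi > biolum.n_bins:
        return None
    if not (biolum.valid[i - 1] and biolum.valid[i]):
        return None
    ref = 0.5 * (biolum.values[i - 1] + biolum.values[i])
    if ref == 0:
        return None
    offsets = np.arange(lo, hi) - i
    return offsets, 100.0 * biolum.values[lo:hi] / ref


def align_and_average(transition_sets: list[TransitionSet],
                      biolums: list[BinnedSignal],
                      direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Mean transition-aligned trace, averaged within then across animals.

    Each animal contributes the mean over its qualifying transitions of the
    given direction; the group trace is the mean across animals.  The
    reported span is truncated to the offsets to which *all* animals
    contribute (the longest pre/post extent common to every animal), so the
    group mean never mixes different animal subsets.

    Returns ``(offset_minutes, percent)``; offset 0 marks the first 3-min
    block of the new state (bin start at the transition boundary).
    """
    if len(transition_sets) != len(biolums):
        raise ValueError("one TransitionSet per animal required")
    per_animal: list[dict[int, float]] = []
    for ts, bl in zip(transition_sets, biolums):
        traces: dict[int, list[float]] = {}
        for tr in ts.by_direction(direction):
            out = align_transition(bl, tr, ts.start_time)
            if out is None:
                continue
            for off, val in zip(*out):
                traces.setdefault(int(off), []).append(float(val))
        if traces:
            per_animal.append({k: float(np.mean(v)) for k, v in traces.items()})
    if not per_animal:
        return np.array([]), np.array([])
    lo = max(min(d) for d in per_animal)
    hi = min(max(d) for d in per_animal)
    offsets = np.arange(lo, hi + 1)
    mean = np.array([np.mean([d[o] for d in per_animal]) for o in offsets])
    return offsets * BLOCK_MIN, mean


def state_fractions(epochs: EpochSeries,
                    window: tuple[float, float] | None = None) -> dict[str, float]:
    """Fractions of recording time spent in wake / NREM / REM."""
    states = epochs.states
    if window is not None:
        t = epochs.times_h
        m = (t >= window[0] - 1e-9) & (t < window[1] - 1e-9)
        if not m.any():
            raise ValueError("window outside the hypnogram support")
        states = states[m]
    n = states.size
    return {
        "wake": float(np.sum(states == WAKE)) / n,
        "nrem": float(np.sum(states == NREM)) / n,
        "rem": float(np.sum(states == REM)) / n,
    }


def wake_per_bin(epochs: EpochSeries, bin_h: float) -> BinnedSignal:
    """Minutes spent awake per bin of ``bin_h`` hours."""
    per = bin_h * 3600.0 / epochs.epoch_len
    k = round(per)
    if not np.isclose(per, k, rtol=1e-9):
        raise ValueError("bin width must be a multiple of the epoch length")
    n = epochs.n_epochs // k
    if n * k != epochs.n_epochs:
        raise ValueError("hypnogram support is not a multiple of the bin width")
    wake = epochs.is_wake()[: n * k].reshape(n, k)
    minutes = wake.sum(axis=1) * epochs.epoch_len / 60.0
    return BinnedSignal(start_time=epochs.start_time, bin_width=bin_h,
                        values=minutes, units="min awake")


def hourly_wake(epochs: EpochSeries) -> BinnedSignal:
    """Minutes awake per hour."""
    return wake_per_bin(epochs, 1.0)


def wake_per_4h(epochs: EpochSeries) -> BinnedSignal:
    """Minutes awake per consecutive 4-h interval (SD + SOW resolution)."""
    return wake_per_bin(epochs, 4.0)
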