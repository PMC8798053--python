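"""Hypnogram analysis: block classification, sustained-transition selection
(checked against a brute-force oracle), aligned traces, wake statistics."""

import numpy as np
import pytest

from per2osc.core import BinnedSignal, EpochSeries
from per2osc.hypno import (BLOCK_MIN, align_and_average, align_transition,
                           classify_3min_intervals, hourly_wake,
                           select_transitions, state_fractions, wake_per_4h)
from per2osc.sinefit import fit_sine


def epochs_from_counts(wake_counts):
    """Build 4-s epochs with the given number of wake epochs per 45-block."""
    states = []
    for c in wake_counts:
        states += ["W"] * c + ["N"] * (45 - c)
    return EpochSeries(0.0, 4.0, np.array(states, dtype="U1"))


def oracle_transitions(blocks, min_pre=3, min_post=5):
    """Brute-force reference: scan run lengths around every index."""
    out = []
    n = len(blocks)
    for i in range(1, n):
        if blocks[i] == blocks[i - 1]:
            continue
        pre = 0
        j = i - 1
        while j >= 0 and blocks[j] == blocks[i - 1]:
            pre += 1
            j -= 1
        post = 0
        j = i
        while j < n and blocks[j] == blocks[i]:
            post += 1
            j += 1
        if pre >= min_pre and post >= min_post:
            out.append((i, bool(blocks[i]), pre, post))
    return out


class TestClassification:
    @pytest.mark.parametrize("count,expect_wake", [
        (23, True), (22, False), (45, True), (0, False),
    ])
    def test_majority_threshold(self, count, expect_wake):
        blocks = classify_3min_intervals(epochs_from_counts([count]))
        assert blocks[0] == expect_wake

    def test_rem_counts_as_sleep(self):
        states = np.array(["R"] * 45, dtype="U1")
        assert not classify_3min_intervals(EpochSeries(0.0, 4.0, states))[0]

    def test_wrong_epoch_length_rejected(self):
        states = np.array(["W"] * 45, dtype="U1")
        with pytest.raises(ValueError):
            classify_3min_intervals(EpochSeries(0.0, 8.0, states))

    def test_non_multiple_length_rejected(self):
        states = np.array(["W"] * 46, dtype="U1")
        with pytest.raises(ValueError):
            classify_3min_intervals(EpochSeries(0.0, 4.0, states))


class TestSelectTransitions:
    def test_single_qualifying_transition_with_full_extents(self):
        blocks = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1], dtype=bool)
        ts = select_transitions(blocks)
        assert len(ts.transitions) == 1
        tr = ts.transitions[0]
        assert tr.direction == "sleep_to_wake"
        assert tr.pre_extent_min == 12.0
        assert tr.post_extent_min == 18.0

    def test_constant_sequence_has_no_transitions(self):
        assert not select_transitions(np.ones(20, dtype=bool)).transitions

    @pytest.mark.parametrize("seq,n_expected", [
        ([0, 0, 0, 1, 1, 1, 1, 1], 1),   # pre run 3, post run 5 qualifies
        ([0, 0, 1, 1, 1, 1, 1], 0),      # pre run 2 < 3
    ])
    def test_boundary_run_lengths(self, seq, n_expected):
        ts = select_transitions(np.array(seq, dtype=bool))
        assert len(ts.transitions) == n_expected

    def test_agrees_with_oracle_on_random_sequences(self):
        """Exact agreement with the brute-force scan on 1,000 sequences."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(8, 60)
            blocks = rng.random(n) < rng.uniform(0.2, 0.8)
            got = [(t.index, t.direction == "sleep_to_wake", t.pre_blocks,
                    t.post_blocks)
                   for t in select_transitions(blocks).transitions]
            assert got == oracle_transitions(list(blocks))

    def test_same_direction_neighbors_split_by_disqualified_reversal(self):
        """Two consecutive qualifying transitions of the same direction are
        always separated by at least one state change that fails the run
        criteria (otherwise the intermediate reversal would itself qualify
        and the directions would alternate)."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            blocks = rng.random(rng.integers(10, 80)) < 0.5
            trs = select_transitions(blocks).transitions
            changes = set(np.flatnonzero(np.diff(blocks)) + 1)
            for a, b in zip(trs, trs[1:]):
                if a.direction == b.direction:
                    between = [i for i in changes if a.index < i < b.index]
                    assert between, "same direction with no reversal between"


class TestAlignAndAverage:
    def biolum_3min(self, values):
        return BinnedSignal(0.0, BLOCK_MIN / 60.0, np.asarray(values, float))

    def test_reference_is_mean_of_flanking_bins(self):
        blocks = np.array([0, 0, 0, 1, 1, 1, 1, 1], dtype=bool)
        ts = select_transitions(blocks)
        bl = self.biolum_3min([0.9, 0.9, 0.9, 1.1, 1.05, 1.1, 1.1, 1.1])
        off, vals = align_transition(bl, ts.transitions[0], 0.0)
        ref = 0.5 * (0.9 + 1.1)
        assert vals[np.where(off == -1)[0][0]] == pytest.approx(90.0)
        assert vals[np.where(off == 0)[0][0]] == pytest.approx(110.0)
        assert vals[np.where(off == 1)[0][0]] == pytest.approx(105.0 / ref * 1.0)

    def test_flat_signal_gives_100_percent(self):
        blocks = np.array([0, 0, 0, 1, 1, 1, 1, 1], dtype=bool)
        ts = select_transitions(blocks)
        bl = self.biolum_3min(np.full(8, 0.7))
        off, vals = align_and_average([ts], [bl], "sleep_to_wake")
        assert np.allclose(vals, 100.0)

    def test_flanking_bins_average_to_100(self):
        """By construction of the reference, bins -1 and 0 average to 100%."""
        rng = np.random.default_rng(3)
        blocks = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 0, 0, 0, 1, 1, 1,
                           1, 1], dtype=bool)
        ts = select_transitions(blocks)
        bl = self.biolum_3min(1.0 + 0.1 * rng.standard_normal(blocks.size))
        off, vals = align_and_average([ts], [bl], "sleep_to_wake")
        i_pre = np.where(off == -BLOCK_MIN)[0][0]
        i_post = np.where(off == 0.0)[0][0]
        assert 0.5 * (vals[i_pre] + vals[i_post]) == pytest.approx(100.0,
                                                                   abs=1e-9)

    def test_truncated_to_common_extent_across_animals(self):
        blocks_a = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 1], dtype=bool)
        blocks_b = np.array([0, 0, 0, 1, 1, 1, 1, 1, 0, 0], dtype=bool)
        ts_a, ts_b = select_transitions(blocks_a), select_transitions(blocks_b)
        bl = self.biolum_3min(np.ones(10))
        off, vals = align_and_average([ts_a, ts_b], [bl, bl], "sleep_to_wake")
        assert off.max() == (5 - 1) * BLOCK_MIN  # animal B caps the post extent

    def test_wake_force_raises_trace_after_transition(self, scnx_params):
        """With a positive wake force and no noise, the mean sleep-to-wake
        trace rises above its reference level during sustained waking."""
        from per2osc.synth import (SynthConfig, gen_hypnogram, gen_lma,
                                   gen_bioluminescence)
        from per2osc.protocols import no_protocol
        # pure wake force (A = 0), stationary sleep-wake statistics: the
        # trace shape then reflects the wake force alone
        scnx_params = scnx_params.replace(A=0.0)
        cfg = SynthConfig(duration_h=96.0, noise_sd=0.0,
                          circadian_modulation=0.0, seed=21)
        epochs = gen_hypnogram(cfg)
        lma = gen_lma(epochs, cfg)
        _, traj = gen_bioluminescence(lma, scnx_params, cfg, no_protocol(96.0))
        # sample the noise-free trajectory onto the 3-min analysis grid
        t3 = np.arange(96.0 / (BLOCK_MIN / 60.0)) * BLOCK_MIN / 60.0 \
            + 0.5 * BLOCK_MIN / 60.0
        sig = self.biolum_3min(
            scnx_params.intercept + np.interp(t3, traj.t, traj.x1))
        blocks = classify_3min_intervals(epochs)
        ts = select_transitions(blocks)
        off, vals = align_and_average([ts], [sig], "sleep_to_wake")
        late = vals[off >= 6.0]
        assert late.size > 0
        assert vals[off == off.max()][0] > 100.0
        assert np.all(np.diff(late) > -1.0)  # non-decreasing up to wiggle


class TestWakeStatistics:
    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        states = rng.choice(list("WNR"), size=900)
        f = state_fractions(EpochSeries(0.0, 4.0, states))
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)

    def test_pure_and_mixed_fractions(self):
        all_wake = EpochSeries(0.0, 4.0, np.full(900, "W", dtype="U1"))
        assert state_fractions(all_wake) == {"wake": 1.0, "nrem": 0.0,
                                             "rem": 0.0}
        half = EpochSeries(0.0, 4.0,
                           np.array(["W"] * 450 + ["N"] * 450, dtype="U1"))
        f = state_fractions(half)
        assert f["wake"] == f["nrem"] == 0.5

    def test_hourly_wake_extremes(self):
        all_wake = EpochSeries(0.0, 4.0, np.full(900 * 4, "W", dtype="U1"))
        assert np.allclose(hourly_wake(all_wake).values, 60.0)
        assert np.allclose(wake_per_4h(all_wake).values, 240.0)

    def test_alternating_blocks_give_half_wake(self):
        pattern = (["W"] * 45 + ["N"] * 45) * 10
        ep = EpochSeries(0.0, 4.0, np.array(pattern, dtype="U1"))
        assert np.allclose(hourly_wake(ep).values, 30.0)

    def test_circadian_hypnogram_rhythmic_by_permutation_test(self):
        """4-h wake totals of a modulated hypnogram carry a sinewave
        amplitude exceeding the block-permutation null (p < 0.01)."""
        from per2osc.synth import SynthConfig, gen_hypnogram
        cfg = SynthConfig(duration_h=96.0, circadian_modulation=0.8, seed=17)
        wake4 = wake_per_4h(gen_hypnogram(cfg))
        t = wake4.mid_times_h
        a_obs = fit_sine(t, wake4.values, period=cfg.circadian_period_h).a
        rng = np.random.default_rng(1)
        null = [fit_sine(t, rng.permutation(wake4.values),
                         period=cfg.circadian_period_h).a
                for _ in range(199)]
        p = (1 + sum(a >= a_obs for a in null)) / 200.0
        assert p < 0.01
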