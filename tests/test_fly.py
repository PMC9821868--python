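import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bruteforce_sleep_minutes
from sleepv2g.fly import (
    ActivityTrace,
    StimulusEvent,
    arousal_threshold,
    call_screen_hits,
    compare_reactivity,
    compare_rebound,
    immobility_duration_min,
    is_dead,
    percent_rebound,
    pool_reactivity,
    reactivity,
    score_fly_sleep,
    summarize_fly_sleep,
)


class TestScoring:
    @pytest.mark.parametrize(
        "counts,sleep_min,n_bouts",
        [
            ([1, 0, 0, 0, 0, 1], 0, 0),  # 4-min immobility is not sleep
            ([1, 0, 0, 0, 0, 0, 1], 5, 1),
            ([0] * 1440, 1440, 1),
            ([0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0], 10, 2),  # truncated final run counts
        ],
    )
    def test_five_minute_rule(self, counts, sleep_min, n_bouts):
        state, bouts = score_fly_sleep(np.array(counts))
        assert int(state.sum()) == sleep_min
        assert len(bouts) == n_bouts

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            score_fly_sleep(np.array([1, -1, 0]))

    def test_exhaustive_short_traces_match_oracle(self):
        for n in range(1, 13):
            for bits in itertools.product([0, 1], repeat=n):
                state, _ = score_fly_sleep(np.array(bits))
                assert list(state) == bruteforce_sleep_minutes(bits)

    def test_random_traces_match_oracle(self, rng):
        for _ in range(200):
            counts = rng.poisson(0.7, size=int(rng.integers(10, 200)))
            state, _ = score_fly_sleep(counts)
            assert list(state) == bruteforce_sleep_minutes(list(counts))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=64), st.integers(1, 9))
    def test_scale_invariance_and_conservation(self, counts, scale):
        counts = np.array(counts)
        state, _ = score_fly_sleep(counts)
        scaled_state, _ = score_fly_sleep(counts * scale)
        assert np.array_equal(state, scaled_state)  # only the zero pattern matters
        assert state.sum() + (~state).sum() == counts.size

    def test_adding_activity_never_increases_sleep(self, rng):
        counts = rng.poisson(0.5, size=300)
        base = score_fly_sleep(counts)[0].sum()
        for _ in range(30):
            bumped = counts.copy()
            bumped[rng.integers(300)] += 1
            assert score_fly_sleep(bumped)[0].sum() <= base


class TestSummary:
    def test_waking_activity_arithmetic(self):
        counts = np.concatenate([np.zeros(600, dtype=int), np.full(840, 2)])
        trace = ActivityTrace("f1", "ctl", counts)
        state, bouts = score_fly_sleep(counts)
        s = summarize_fly_sleep(state, trace, bouts)
        assert s.waking_activity == pytest.approx(2.0)
        assert s.total_sleep_min == 600
        assert s.day_sleep_min == 600 and s.night_sleep_min == 0
        assert s.day_sleep_min + s.night_sleep_min == s.total_sleep_min

    def test_all_sleep_day_flags_undefined_activity(self):
        trace = ActivityTrace("f1", "ctl", np.zeros(1440, dtype=int))
        state, bouts = score_fly_sleep(trace.counts)
        s = summarize_fly_sleep(state, trace, bouts)
        assert (s.day_sleep_min, s.night_sleep_min) == (720, 720)
        assert s.waking_activity is None

    def test_multiday_average_and_recomputation(self, rng):
        counts = rng.poisson(0.8, size=2 * 1440)
        trace = ActivityTrace("f1", "ctl", counts)
        state, bouts = score_fly_sleep(counts)
        s = summarize_fly_sleep(state, trace, bouts)
        zt = trace.zt_minutes()
        assert s.total_sleep_min == pytest.approx(state.sum() / 2)
        assert s.day_sleep_min == pytest.approx(state[zt < 720].sum() / 2)
        assert s.waking_activity == pytest.approx(counts[~state].sum() / (~state).sum())

    def test_misaligned_lengths_error(self):
        trace = ActivityTrace("f1", "ctl", np.ones(10, dtype=int))
        with pytest.raises(ValueError):
            summarize_fly_sleep(np.zeros(9, dtype=bool), trace)

    def test_dead_animal_flag(self):
        alive = np.concatenate([np.ones(1440, dtype=int), np.zeros(1000, dtype=int),
                                np.ones(10, dtype=int)])
        dead = np.concatenate([np.ones(1440, dtype=int), np.zeros(1500, dtype=int)])
        assert not is_dead(alive)
        assert is_dead(dead)


class TestScreen:
    def test_band_rule(self):
        lines = {"long": [730] * 4, "short": [470] * 4}
        # reference pool with mean 600, SD ~57: band is roughly [487, 713]
        pool = list(600 + 50 * np.array([-1, 1, -1, 1, -1.5, 1.5, -0.5, 0.5]))
        lines["ctl"] = pool
        calls = {c.line_id: c for c in call_screen_hits(lines, ["ctl"], k_sd=2.0)}
        sd = np.std(pool, ddof=1)
        assert calls["ctl"].band_high == pytest.approx(600 + 2 * sd)
        assert calls["long"].call == "long"
        assert calls["short"].call == "short"
        assert calls["ctl"].call == "none"

    def test_translation_equivariance(self, rng):
        lines = {f"l{i}": list(rng.normal(600, 50, 8)) for i in range(4)}
        shifted = {k: [v + 123.0 for v in vals] for k, vals in lines.items()}
        a = call_screen_hits(lines)
        b = call_screen_hits(shifted)
        for ca, cb in zip(a, b):
            assert cb.band_low == pytest.approx(ca.band_low + 123.0)
            assert cb.band_high == pytest.approx(ca.band_high + 123.0)
            assert ca.call == cb.call

    def test_reference_pool_errors(self):
        with pytest.raises(ValueError):
            call_screen_hits({"a": [1.0]}, "all_animals")
        with pytest.raises(ValueError):
            call_screen_hits({"a": [1.0, 2.0]}, ["missing"])


class TestRebound:
    def test_percent_change(self):
        pct, excluded = percent_rebound([200.0, 100.0, 0.0], [260.0, 100.0, 50.0])
        assert pct == pytest.approx([30.0, 0.0])
        assert excluded == [2]

    def test_equal_rebound_centered_at_zero(self, rng):
        base_a, base_b = rng.uniform(150, 350, 40), rng.uniform(150, 350, 40)
        rec_a = base_a * rng.normal(1.3, 0.05, 40)
        rec_b = base_b * rng.normal(1.3, 0.05, 40)
        res = compare_rebound(percent_rebound(base_a, rec_a)[0],
                              percent_rebound(base_b, rec_b)[0])
        assert abs(res.mean_difference) < 4 * res.se


def escalating_trial(start_min, intensities=(0.3, 0.6, 0.9, 1.2), gap_min=2):
    return [StimulusEvent((start_min + i * gap_min) * 60, g)
            for i, g in enumerate(intensities)]


class TestArousal:
    def make(self, n_min=60, asleep_from=0):
        sleep = np.zeros(n_min, dtype=bool)
        sleep[asleep_from:] = True
        movement = np.zeros(n_min * 60)
        return sleep, movement

    def test_threshold_is_lowest_responding_intensity(self):
        sleep, movement = self.make()
        trial = escalating_trial(10)
        movement[trial[3].time_s + 5] = 4.0  # responds only at 1.2 g
        (res,) = arousal_threshold(movement, [trial], sleep)
        assert not res.excluded and res.threshold_g == 1.2

    def test_awake_at_onset_excluded(self):
        sleep, movement = self.make(asleep_from=30)
        (res,) = arousal_threshold(movement, [escalating_trial(10)], sleep)
        assert res.excluded and res.threshold_g is None

    def test_no_response_censored(self):
        sleep, movement = self.make()
        (res,) = arousal_threshold(movement, [escalating_trial(10)], sleep)
        assert res.censored and res.threshold_g is None

    def test_subthreshold_movement_is_no_response(self):
        sleep, movement = self.make()
        trial = escalating_trial(10)
        movement[trial[0].time_s + 3] = 2.9  # 3 mm rule is strict
        (res,) = arousal_threshold(movement, [trial], sleep)
        assert res.censored

    def test_nonmonotonic_intensities_error(self):
        sleep, movement = self.make()
        bad = [StimulusEvent(600, 1.2), StimulusEvent(720, 0.6)]
        with pytest.raises(ValueError):
            arousal_threshold(movement, [bad], sleep)


class TestReactivity:
    def test_proportion_per_bin(self):
        # ten flies asleep 7 minutes at stimulus onset; 7 respond
        tables = []
        for i in range(10):
            sleep = np.zeros(20, dtype=bool)
            sleep[3:] = True  # immobile since minute 3; stimulus at minute 9 -> 7 min
            movement = np.zeros(20 * 60)
            if i < 7:
                movement[9 * 60 + 10] = 5.0
            tables.append(reactivity(movement, [StimulusEvent(9 * 60, 1.2)], sleep))
        pooled = pool_reactivity(tables)
        assert pooled.loc[0, "trials"] == 10
        assert pooled.loc[0, "proportion"] == pytest.approx(0.7)
        assert pooled.loc[0, "bin_low"] == 5

    def test_zero_trial_bins_omitted(self):
        sleep = np.zeros(20, dtype=bool)
        sleep[0:14] = True
        tab = reactivity(np.zeros(20 * 60), [StimulusEvent(13 * 60, 1.2)], sleep)
        assert list(tab["bin_low"]) == [10]  # only the 10-15 bin appears

    def test_identical_groups_effect_near_zero(self, rng):
        def table(seed):
            r = np.random.default_rng(seed)
            rows = []
            for lo in (5, 10, 15, 20):
                n = 50
                k = r.binomial(n, 0.8 - 0.02 * lo)
                rows.append({"bin_low": lo, "bin_high": lo + 5, "bin_mid": lo + 2.5,
                             "trials": n, "responders": k, "proportion": k / n})
            import pandas as pd

            return pd.DataFrame(rows)

        effects = [compare_reactivity(table(2 * s), table(2 * s + 1))[0] for s in range(20)]
        assert abs(np.mean(effects)) < 0.05

    def test_immobility_duration_helper(self):
        sleep = np.array([False, True, True, True, False, True])
        assert immobility_duration_min(sleep, 3) == 3
        assert immobility_duration_min(sleep, 0) == 0
        assert immobility_duration_min(sleep, 5) == 1
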