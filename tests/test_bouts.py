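import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circalarva.bouts import (
    bout_ecdf,
    classify_bins,
    compute_rest_stats,
    estimate_rest_threshold,
    segment_bouts,
    total_activity,
)
from circalarva.bouts import EcdfCurve
from circalarva.model import ActivityTrack, CircalarvaError
from circalarva.simulate import simulate_crossover_bouts
from conftest import brute_force_rle


def _track(dist, bw=1.0):
    return ActivityTrack("t", "WT", bw, np.asarray(dist, dtype=float))


class TestClassifyBins:
    def test_zero_distances_are_immobile(self):
        assert not classify_bins(_track(np.zeros(10))).any()

    def test_epsilon_boundary_is_strict(self):
        out = classify_bins(_track([0.0, 0.2, 0.0]), 0.0)
        assert out.tolist() == [False, True, False]
        # distance exactly equal to epsilon is immobile
        assert classify_bins(_track([0.05]), 0.05).tolist() == [False]

    def test_matches_elementwise_comparison_on_random_input(self):
        rng = np.random.default_rng(42)
        d = rng.uniform(0, 0.2, 10_000)
        assert np.array_equal(classify_bins(_track(d), 0.05), d > 0.05)

    def test_requires_one_second_bins(self):
        with pytest.raises(CircalarvaError):
            classify_bins(_track(np.ones(10), bw=600.0))


class TestSegmentBouts:
    def test_single_immobile_run(self):
        bt = segment_bouts(np.zeros(600, dtype=bool), 1.0, np.zeros(600))
        assert bt.n_bouts == 1
        assert bt.states[0] == "immobile" and bt.duration_s[0] == 600

    def test_three_run_pattern(self):
        seq = np.r_[np.ones(30), np.zeros(90), np.ones(10)].astype(bool)
        bt = segment_bouts(seq, 1.0, np.where(seq, 1.0, 0.0))
        assert bt.states.tolist() == ["active", "immobile", "active"]
        assert bt.duration_s.tolist() == [30, 90, 10]
        assert bt.distance_mm.tolist() == [30, 0, 10]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=300))
    def test_equals_brute_force_rle(self, seq):
        seq = np.array(seq, dtype=bool)
        dist = np.where(seq, 1.0, 0.0)
        bt = segment_bouts(seq, 1.0, dist)
        expected = brute_force_rle(seq.tolist())
        assert bt.n_bouts == len(expected)
        for i, (active, start, length) in enumerate(expected):
            assert (bt.states[i] == "active") == active
            assert bt.start_s[i] == start
            assert bt.duration_s[i] == length
        # partition identity: durations tile the sequence exactly
        assert bt.duration_s.sum() == seq.size
        assert np.all(bt.start_s[1:] == bt.start_s[:-1] + bt.duration_s[:-1])


class TestBoutEcdf:
    def test_small_example(self):
        e = bout_ecdf([10, 10, 20])
        assert np.allclose(e.lengths_s, [10, 20])
        assert np.allclose(e.cum_prob, [2 / 3, 1.0])

    def test_single_length_steps_to_one(self):
        e = bout_ecdf([42])
        assert e.cum_prob.tolist() == [1.0]

    def test_matches_sort_and_count_oracle(self):
        rng = np.random.default_rng(1)
        lengths = rng.integers(1, 500, 5000)
        e = bout_ecdf(lengths)
        sorted_l = np.sort(lengths)
        for L, p in zip(e.lengths_s, e.cum_prob):
            assert p == pytest.approx(np.searchsorted(sorted_l, L, "right") / 5000)
        assert e.cum_prob[-1] == 1.0
        assert np.all(np.diff(e.cum_prob) >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(CircalarvaError):
            bout_ecdf([])


class TestRestThreshold:
    def test_noiseless_broken_power_law_recovers_sixty_exactly(self):
        L = np.unique(np.round(np.logspace(0, 2.8, 400)))
        surv = np.where(L <= 60, L**-0.5, 60**-0.5 * (L / 60) ** -2.5)
        e = EcdfCurve(lengths_s=L, cum_prob=1 - surv, counts=np.ones_like(L), n=10**9)
        est = estimate_rest_threshold(e)
        assert est.valid
        assert est.threshold_s == pytest.approx(60.0, abs=1e-6)

    def test_sampled_crossover_recovered_within_15s(self):
        hits = 0
        for s in range(20):
            est = estimate_rest_threshold(bout_ecdf(simulate_crossover_bouts(5000, seed=500 + s)))
            hits += 45 <= est.threshold_s <= 75
        assert hits >= 18

    def test_single_exponential_is_not_a_crossover(self):
        rng = np.random.default_rng(7)
        lengths = np.maximum(np.round(rng.exponential(30, 5000)), 1)
        est = estimate_rest_threshold(bout_ecdf(lengths))
        assert not est.valid

    def test_too_few_lengths_directs_to_default(self):
        with pytest.raises(CircalarvaError, match="60 s"):
            estimate_rest_threshold(bout_ecdf([10, 20, 30, 600]))


class TestRestStats:
    def test_toy_worked_example(self, toy_bouts):
        st_ = compute_rest_stats(toy_bouts, 60.0, (0.0, 600.0))
        assert st_.resting_time_h_per_day == pytest.approx(4.8)
        assert st_.n_active_rest_cycles == 1
        assert st_.mean_active_period_length_h == pytest.approx(240 / 3600)
        assert st_.mean_distance_per_active_period_mm == pytest.approx(77.5)

    def test_fully_immobile_window(self):
        bt = segment_bouts(np.zeros(86400, dtype=bool), 1.0, np.zeros(86400))
        st_ = compute_rest_stats(bt, 60.0, (0.0, 86400.0))
        assert st_.resting_time_h_per_day == pytest.approx(24.0)
        assert st_.n_active_rest_cycles == 1
        assert np.isnan(st_.mean_active_period_length_h)
        assert np.isnan(st_.mean_distance_per_active_period_mm)

    def test_rest_plus_active_time_partitions_window(self, toy_bouts):
        st_ = compute_rest_stats(toy_bouts, 60.0, (0.0, 600.0))
        rest_s = st_.resting_time_h_per_day / 24.0 * 600.0
        # 2 complete active periods of mean 240 s
        assert rest_s + 2 * 240.0 == pytest.approx(600.0)

    def test_resting_time_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        seq = rng.random(20_000) < 0.6
        bt = segment_bouts(seq, 1.0, np.where(seq, 1.0, 0.0))
        rests = [
            compute_rest_stats(bt, theta, (0.0, 20_000.0)).resting_time_h_per_day
            for theta in (1, 2, 5, 10, 30, 60)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rests, rests[1:]))

    def test_window_shorter_than_threshold_rejected(self, toy_bouts):
        with pytest.raises(CircalarvaError):
            compute_rest_stats(toy_bouts, 60.0, (0.0, 30.0))


class TestTotalActivity:
    def test_zero_track(self):
        tr = _track(np.zeros(86400 * 2))
        assert total_activity(tr, (0, 2)) == 0.0

    def test_constant_rate_arithmetic(self):
        tr = _track(np.ones(86400 * 2))
        assert total_activity(tr, (0, 2)) == pytest.approx(172_800.0)

    def test_invariant_to_rebinning(self):
        from circalarva.rhythm import rebin_activity

        rng = np.random.default_rng(9)
        tr = _track(rng.exponential(0.3, 86400))
        coarse = rebin_activity(tr, 600.0)
        assert total_activity(tr, (0, 1)) == pytest.approx(total_activity(coarse, (0, 1)))

    def test_empty_window_rejected(self):
        with pytest.raises(CircalarvaError):
            total_activity(_track(np.ones(100)), (2, 3))
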