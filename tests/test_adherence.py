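"""Adherence metrics: gaps, compliance, cue response rates.

The brute-force oracle used here re-derives every cue outcome by scanning
each (cue, epoch) pair directly, independently of the vectorized code path.
"""

import math

import numpy as np
import pytest

from souvenir import AccelStream, SessionSchedule
from souvenir.adherence import (
    CueResponseResult,
    aggregate_participant_rates,
    cue_response_rate,
    cue_response_result,
    detect_gaps,
    pre_cue_activity_rate,
    response_curve_by_cue_index,
    schedule_cue_count,
    system_compliance,
    wear_time_compliance,
)
from souvenir.types import CueEventLog, EpochActivitySeries


def _series(active_epochs, n_epochs, side="MI", start=0):
    active = np.zeros(n_epochs, dtype=bool)
    for e in active_epochs:
        active[e] = True
    sums = np.where(active, 1.0, 0.0)
    return EpochActivitySeries(
        side=side, epoch_start_times=start + np.arange(n_epochs),
        magnitude_sum=sums, active=active,
        missing=np.zeros(n_epochs, dtype=bool), threshold=0.5,
    )


def _cues(times, schedule=None):
    sess = [0] * len(times) if schedule is None else \
        [schedule.session_of(t) or 0 for t in times]
    return CueEventLog(t=np.asarray(times, float), session_index=sess,
                       cue_index_in_day=np.arange(1, len(times) + 1))


def brute_force_rates(active, cue_times, window=5, min_active=1, series_start=0):
    """Independent oracle: explicit per-cue scan over epoch windows."""
    n = len(active)
    post_hits = post_n = pre_hits = pre_n = 0
    for t in cue_times:
        p0 = math.ceil(t) - series_start
        if 0 <= p0 and p0 + window <= n:
            post_n += 1
            count = sum(1 for k in range(p0, p0 + window) if active[k])
            post_hits += count >= min_active
        q0 = math.floor(t) - window - series_start
        if 0 <= q0 and q0 + window <= n:
            pre_n += 1
            count = sum(1 for k in range(q0, q0 + window) if active[k])
            pre_hits += count >= min_active
    return (post_hits / post_n if post_n else None,
            pre_hits / pre_n if pre_n else None)


class TestDetectGaps:
    def test_continuous_data_no_gaps(self):
        t = np.arange(0, 300, 1.0)
        assert detect_gaps(t) == []

    def test_gap_found_by_successive_difference(self):
        t = np.concatenate([np.arange(0, 31, 1.0), np.arange(95, 201, 1.0)])
        gaps = detect_gaps(t)
        assert gaps == [(30.0, 95.0)]
        assert gaps[0][1] - gaps[0][0] == 65.0

    def test_59_9s_hole_is_not_a_gap(self):
        t = np.array([0.0, 10.0, 69.9, 80.0])
        assert detect_gaps(t) == []

    def test_exactly_60s_counts(self):
        t = np.array([0.0, 60.0, 61.0])
        assert detect_gaps(t) == [(0.0, 60.0)]

    def test_fewer_than_two_samples_is_whole_window(self):
        assert detect_gaps(np.array([100.0]), window=(0, 300)) == [(0, 300)]
        assert detect_gaps(np.array([]), window=(0, 300)) == [(0, 300)]

    def test_window_edges_count(self):
        t = np.arange(100, 200, 1.0)
        gaps = detect_gaps(t, window=(0.0, 200.0))
        assert gaps == [(0.0, 100.0)]


class TestWearTimeCompliance:
    def _stream(self, t):
        z = np.zeros(len(t))
        return AccelStream("MI", t, z, z, z)

    def test_gap_free_8h_is_100(self):
        t = np.arange(0, 28801, 1.0)
        c = wear_time_compliance(self._stream(t), (0, 28800))
        assert c.compliance_pct == 100.0

    def test_120s_gap_arithmetic(self):
        t = np.concatenate([np.arange(0, 10001, 1.0), np.arange(10120, 28801, 1.0)])
        c = wear_time_compliance(self._stream(t), (0, 28800))
        assert c.compliance_pct == pytest.approx((28800 - 120) / 28800 * 100)
        assert c.compliance_pct == pytest.approx(99.5833, abs=1e-3)

    def test_no_data_is_0(self):
        c = wear_time_compliance(np.array([]), (0, 28800))
        assert c.compliance_pct == 0.0

    def test_sub_60s_gap_changes_nothing(self):
        t = np.concatenate([np.arange(0, 10001, 1.0), np.arange(10059, 28801, 1.0)])
        c = wear_time_compliance(self._stream(t), (0, 28800))
        assert c.compliance_pct == 100.0

    def test_monotone_in_gap_time(self):
        base = np.arange(0, 28801, 1.0)
        prev = 100.0
        for gap in (60, 300, 3600, 20000):
            t = base[(base < 5000) | (base >= 5000 + gap)]
            c = wear_time_compliance(self._stream(t), (0, 28800))
            assert c.compliance_pct <= prev
            prev = c.compliance_pct

    def test_system_compliance_unions_gaps(self):
        mi_t = np.concatenate([np.arange(0, 1001, 1.0), np.arange(1100, 28801, 1.0)])
        li_t = np.concatenate([np.arange(0, 2001, 1.0), np.arange(2200, 28801, 1.0)])
        z = lambda t: AccelStream("MI", t, np.zeros(len(t)), np.zeros(len(t)), np.zeros(len(t)))
        c = system_compliance(z(mi_t), z(li_t), (0, 28800))
        # MI gap (1000, 1100) and LI gap (2000, 2200) are disjoint: union 300 s
        assert c.non_wear_s == pytest.approx(300)
        assert c.compliance_pct == pytest.approx((28800 - 300) / 28800 * 100)


class TestCueResponseRate:
    def _sched(self):
        return SessionSchedule(window_start=0, window_duration=120,
                               session_starts=[0.0], session_duration=90,
                               inter_cue_interval=30)

    def test_spec_example_one_of_three(self):
        """Cues at 0/30/60; activity at epochs 2-3 and 66 -> only cue 1 responds."""
        sched = self._sched()
        series = _series([2, 3, 66], 120)
        cues = _cues([0.0, 30.0, 60.0], sched)
        rate = cue_response_rate(series, cues, sched)
        assert rate == pytest.approx(1 / 3)

    def test_all_epochs_active(self):
        sched = self._sched()
        series = _series(range(120), 120)
        cues = _cues([0.0, 30.0, 60.0], sched)
        assert cue_response_rate(series, cues, sched) == 1.0

    def test_no_active_epochs(self):
        sched = self._sched()
        series = _series([], 120)
        cues = _cues([0.0, 30.0, 60.0], sched)
        assert cue_response_rate(series, cues, sched) == 0.0

    def test_empty_cue_log_raises(self):
        sched = self._sched()
        series = _series([], 120)
        with pytest.raises(ValueError, match="empty cue log"):
            cue_response_rate(series, _cues([]), sched)

    def test_cue_window_past_end_excluded(self):
        sched = self._sched()
        series = _series(range(118), 118)  # series ends before cue 3's window
        cues = _cues([0.0, 30.0, 115.0], sched)
        res = cue_response_result(series, None, cues, sched)
        assert res.n_cues_delivered == 2
        assert res.post_cue_response_rate == 1.0

    def test_cue_in_gap_excluded_symmetrically(self):
        sched = self._sched()
        series = _series(range(120), 120)
        cues = _cues([0.0, 30.0, 60.0], sched)
        res = cue_response_result(series, None, cues, sched, gaps=[(25.0, 95.0)])
        assert res.n_cues_delivered == 1  # cues at 30 and 60 inside the gap
        assert res.per_cue_outcomes[1] == "absent"
        assert res.per_cue_outcomes[2] == "absent"

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sched = self._sched()
        n_epochs = 120
        active = rng.random(n_epochs) < rng.uniform(0.1, 0.9)
        series = _series(np.flatnonzero(active), n_epochs)
        cue_times = np.sort(rng.uniform(6.0, 85.0, size=rng.integers(1, 4)))
        cue_times = np.unique(np.round(cue_times, 1))
        cues = _cues(cue_times, sched)
        res = cue_response_result(series, None, cues, sched)
        post_oracle, pre_oracle = brute_force_rates(active, cue_times)
        assert res.post_cue_response_rate == pytest.approx(post_oracle)
        assert res.pre_cue_activity_rate == pytest.approx(pre_oracle)


class TestPreCueActivityRate:
    def _sched(self):
        return SessionSchedule(window_start=0, window_duration=120,
                               session_starts=[0.0], session_duration=90,
                               inter_cue_interval=30)

    def test_no_activity(self):
        sched = self._sched()
        assert pre_cue_activity_rate(_series([], 120), _cues([30.0, 60.0], sched), sched) == 0.0

    def test_saturated(self):
        sched = self._sched()
        assert pre_cue_activity_rate(_series(range(120), 120),
                                     _cues([30.0, 60.0], sched), sched) == 1.0


class TestResponseCurve:
    def test_single_day_all_responded_flat(self):
        r = CueResponseResult("P", 1, 3, 1.0, 0.0,
                              ["responded"] * 3 + ["absent"] * 177)
        curve = response_curve_by_cue_index([r])
        assert (curve[:3] == 1.0).all()
        assert np.isnan(curve[3:]).all()

    def test_disjoint_days_fill_union(self):
        r1 = CueResponseResult("P", 1, 2, 0.5, 0.0,
                               ["responded", "not"] + ["absent"] * 178)
        r2 = CueResponseResult("P", 2, 2, 1.0, 0.0,
                               ["absent", "absent", "responded", "responded"] + ["absent"] * 176)
        curve = response_curve_by_cue_index([r1, r2])
        np.testing.assert_allclose(curve[:4], [1.0, 0.0, 1.0, 1.0])
        assert np.isnan(curve[4:]).all()

    def test_generator_decay_recovered_by_regression(self, hour_schedule):
        """With multiplicative per-cue decay 0.99, the log response curve's
        fitted slope is negative and within 3 SE of log(0.99)."""
        from souvenir.adherence import detect_gaps
        from souvenir.config import PipelineParams
        from souvenir.pipeline import process_day
        from souvenir.synth import GeneratorParams, generate_day

        params = PipelineParams()
        results = []
        for day_seed in range(12):
            day = generate_day(
                GeneratorParams(seed=1000 + day_seed, p_post=0.9, p_pre=0.0,
                                decay_per_cue=0.99),
                hour_schedule, day_index=day_seed,
            )
            mi, li = process_day(day, params)
            results.append(cue_response_result(mi, li, day.cue_log, day.schedule,
                                               day_index=day_seed))
        n_slots = hour_schedule.cue_count()
        curve = response_curve_by_cue_index(results, n_slots)
        idx = np.arange(n_slots)
        ok = curve > 0
        y = np.log(curve[ok])
        x = idx[ok]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        se = np.sqrt(resid @ resid / (len(x) - 2) / np.sum((x - x.mean()) ** 2))
        assert slope < 0
        assert abs(slope - np.log(0.99)) < 3 * se


class TestScheduleCueCount:
    def test_default_protocol_is_180(self, default_schedule):
        assert schedule_cue_count(default_schedule) == 180

    def test_small_arithmetic(self):
        s = SessionSchedule(window_duration=1200, session_starts=[0],
                            session_duration=600, inter_cue_interval=60)
        assert schedule_cue_count(s) == 10

    def test_interval_longer_than_session_gives_zero(self):
        s = SessionSchedule(window_duration=1200, session_starts=[0],
                            session_duration=60, inter_cue_interval=90)
        assert schedule_cue_count(s) == 0


class TestAggregation:
    @staticmethod
    def _result(pid, day, rate, pre, n=10):
        hits = round(rate * n)
        outcomes = ["responded"] * hits + ["not"] * (n - hits) + ["absent"] * (180 - n)
        return CueResponseResult(pid, day, n, rate, pre, outcomes)

    def test_average_across_days_then_participants(self):
        rs = [
            self._result("A", 1, 0.4, 0.1),
            self._result("A", 2, 0.6, 0.3),
            self._result("B", 1, 1.0, 0.0),
        ]
        agg = aggregate_participant_rates(rs)
        assert agg["A"]["post_cue_response_rate"] == pytest.approx(0.5)
        assert agg["A"]["pre_cue_activity_rate"] == pytest.approx(0.2)
        assert agg["B"]["n_days"] == 1
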