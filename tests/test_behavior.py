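import numpy as np
import pandas as pd
import pytest

from conftest import make_trace
from wormwatcher.behavior import (
    EpochSchedule,
    continuous_stimulated,
    epoch_metrics_table,
    response_duration,
    response_latency,
    spontaneous_and_stimulated,
    survivor_population_curve,
    windowed_means,
)
from wormwatcher.errors import ConfigurationError, InvalidEpochError
from wormwatcher.lifespan import WormRecord


def trace60(values_pre, values_post, epoch_start=0.0):
    """60-s trace with pairs well inside the pre/post windows of epoch 0."""
    pre_starts = epoch_start + 60.0 * np.arange(len(values_pre))
    post_starts = epoch_start + 910.0 + 60.0 * np.arange(len(values_post))
    return make_trace(0, 60, np.concatenate([pre_starts, post_starts]),
                      np.concatenate([values_pre, values_post]))


def trace5(post_values, epoch_start=0.0, offset=0.0):
    """5-s trace covering the post-stimulus window starting at 910 s."""
    starts = epoch_start + 910.0 + offset + 5.0 * np.arange(len(post_values))
    # prepend one pre-stimulus pair so the trace spans the epoch
    starts = np.concatenate([[epoch_start], starts])
    values = np.concatenate([[0], post_values])
    return make_trace(0, 5, starts, values)


class TestSchedule:
    def test_stimulus_must_end_inside_epoch(self):
        with pytest.raises(ConfigurationError):
            EpochSchedule([0.0], epoch_duration_s=900, stimulus_onset_s=895,
                          stimulus_duration_s=10)

    def test_epochs_must_not_overlap(self):
        with pytest.raises(ConfigurationError):
            EpochSchedule([0.0, 1000.0], epoch_duration_s=1800)

    def test_day_labels(self):
        sched = EpochSchedule.twice_daily(6)
        np.testing.assert_array_equal(sched.epoch_days(), [1, 1, 2, 2, 3, 3])

    def test_post_window_is_900s_under_standard_protocol(self):
        assert EpochSchedule.twice_daily(1).post_window_s == 900.0


class TestSpontaneousAndStimulated:
    def test_all_zero_trace(self, standard_schedule):
        tr = trace60([0, 0, 0], [0, 0, 0])
        assert spontaneous_and_stimulated(tr, standard_schedule, 0) == (0, 0)

    def test_hand_built_maxima(self, standard_schedule):
        # [3, 1, 0 | stim | 0, 7, 2] -> spontaneous 3, stimulated 7
        tr = trace60([3, 1, 0], [0, 7, 2])
        assert spontaneous_and_stimulated(tr, standard_schedule, 0) == (3, 7)

    def test_moves_only_after_stimulus(self, standard_schedule):
        tr = trace60([0, 0, 0], [4, 9, 1])
        spont, stim = spontaneous_and_stimulated(tr, standard_schedule, 0)
        assert spont == 0 and stim == 9

    def test_pairs_straddling_stimulus_are_masked(self, standard_schedule):
        # one pair overlapping the flash (870-930 s) with a huge value, plus
        # clean pre/post pairs; the straddler must contribute to neither max
        starts = np.array([0.0, 870.0, 920.0])
        tr = make_trace(0, 60, starts, [2, 999, 5])
        assert spontaneous_and_stimulated(tr, standard_schedule, 0) == (2, 5)

    def test_pair_ending_at_onset_sees_the_flash_and_is_masked(self, standard_schedule):
        tr = make_trace(0, 60, np.array([0.0, 840.0, 920.0]), [2, 999, 5])
        assert spontaneous_and_stimulated(tr, standard_schedule, 0) == (2, 5)

    def test_missing_window_is_error_not_zero(self, standard_schedule):
        only_pre = make_trace(0, 60, np.array([0.0, 60.0]), [1, 2])
        with pytest.raises(InvalidEpochError):
            spontaneous_and_stimulated(only_pre, standard_schedule, 0)

    def test_second_epoch_uses_its_own_window(self, standard_schedule):
        tr = trace60([6, 0], [0, 8], epoch_start=43200.0)
        assert spontaneous_and_stimulated(tr, standard_schedule, 1) == (6, 8)


class TestResponseDuration:
    def test_all_zero_post(self, standard_schedule):
        assert response_duration(trace5(np.zeros(177)), standard_schedule, 0) == 0.0

    def test_24_nonzero_values_give_120s(self, standard_schedule):
        vals = np.zeros(177)
        vals[:24] = 5
        assert response_duration(trace5(vals), standard_schedule, 0) == 120.0

    def test_saturation_when_always_moving(self, standard_schedule):
        # every post-stimulus pair nonzero: the window from stimulus end
        # (910 s) to epoch end holds 178 complete 5-s pairs -> 890 s, the
        # measurable ceiling, never exceeding the nominal 900-s window
        d = response_duration(trace5(np.ones(178)), standard_schedule, 0)
        assert d == 890.0
        assert d <= standard_schedule.post_window_s

    def test_multiple_of_sampling_step(self, standard_schedule):
        rng = np.random.default_rng(0)
        vals = (rng.random(150) < 0.3).astype(int)
        d = response_duration(trace5(vals), standard_schedule, 0)
        assert d % 5 == 0


class TestResponseLatency:
    def test_no_movement_gives_900s_sentinel(self, standard_schedule):
        assert response_latency(trace5(np.zeros(177)), standard_schedule, 0) == 900.0

    def test_immediate_response_gives_zero(self, standard_schedule):
        vals = np.zeros(177)
        vals[0] = 3
        assert response_latency(trace5(vals), standard_schedule, 0) == 0.0

    def test_first_movement_35s_after_stimulus_end(self, standard_schedule):
        vals = np.zeros(177)
        vals[7] = 3  # pair starting at 910 + 35 s
        assert response_latency(trace5(vals), standard_schedule, 0) == 35.0

    def test_latency_is_multiple_of_step_and_bounded(self, standard_schedule):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = (rng.random(177) < 0.05).astype(int)
            lat = response_latency(trace5(vals), standard_schedule, 0)
            assert lat % 5 == 0
            assert 0 <= lat <= standard_schedule.post_window_s


class TestContinuousMode:
    def schedule(self):
        return EpochSchedule([0.0], mode="continuous", stimulus_onset_s=0.0,
                             continuous_stim_period_s=3600.0)

    def test_hourly_stimuli_over_24h_give_23_complete_intervals(self):
        sched = self.schedule()
        starts = 60.0 * np.arange(int(24 * 3600 / 60) - 1)
        tr = make_trace(0, 60, starts, np.zeros(len(starts)))
        out = continuous_stimulated(tr, sched, recording_end_s=24 * 3600.0)
        assert len(out) == 23

    def test_all_zero_trace_gives_zero_series(self):
        sched = self.schedule()
        starts = 60.0 * np.arange(400)
        tr = make_trace(0, 60, starts, np.zeros(400))
        out = continuous_stimulated(tr, sched, recording_end_s=4 * 3600.0)
        assert (out["stimulated"].fillna(0) == 0).all()

    def test_single_burst_lands_in_its_interval(self):
        sched = self.schedule()
        starts = 60.0 * np.arange(24 * 60 - 1)
        vals = np.zeros(len(starts))
        burst_t = 3 * 3600.0 + 1200.0  # between stimuli 3 and 4
        vals[np.argmin(np.abs(starts - burst_t))] = 50
        out = continuous_stimulated(tr := make_trace(0, 60, starts, vals), sched,
                                    recording_end_s=24 * 3600.0)
        nz = out[out["stimulated"].fillna(0) > 0]
        assert list(nz["interval_index"]) == [3]

    def test_fewer_than_two_stimuli_is_error(self):
        sched = self.schedule()
        tr = make_trace(0, 60, 60.0 * np.arange(10), np.zeros(10))
        with pytest.raises(InvalidEpochError):
            continuous_stimulated(tr, sched, recording_end_s=1800.0)


def metrics_frame(rows):
    return pd.DataFrame(rows)


class TestWindowedMeans:
    def base(self, metric_by_epoch, n_days=10, epochs_per_day=2):
        rows = []
        for e, val in enumerate(metric_by_epoch):
            day = e // epochs_per_day + 1
            rows.append(
                dict(well_index=0, epoch_index=e, time_h=12.0 * e, day=day,
                     spontaneous=val, stimulated=val, duration_s=val,
                     latency_s=val, valid=True)
            )
        return metrics_frame(rows)

    def test_constant_metric(self):
        m = self.base([7.0] * 20)
        out = windowed_means(m, [(1, 10)])
        assert out.loc[0, "stimulated"] == 7.0

    def test_metric_equal_to_day_number_averages_to_5p5(self):
        days = np.repeat(np.arange(1, 11), 2)
        m = self.base(days.astype(float))
        out = windowed_means(m, [(1, 10)])
        assert out.loc[0, "stimulated"] == pytest.approx(5.5)

    def test_dead_before_window_yields_missing(self):
        m = self.base([1.0] * 40)
        out = windowed_means(m, [(1, 10), (10, 20)], death_times_h={0: 8 * 24.0})
        w2 = out[out["window"] == "10-20"].iloc[0]
        assert np.isnan(w2["stimulated"])

    def test_empty_window_is_missing_not_zero(self):
        m = self.base([1.0] * 4)  # only days 1-2 present
        out = windowed_means(m, [(5, 9)])
        assert np.isnan(out.loc[0, "stimulated"])


class TestSurvivorPopulationCurve:
    def metrics_for(self, wells_values, n_epochs=4):
        rows = []
        for w, v in wells_values.items():
            for e in range(n_epochs):
                rows.append(
                    dict(well_index=w, epoch_index=e, time_h=12.0 * e, day=e // 2 + 1,
                         spontaneous=v, stimulated=v, duration_s=0.0,
                         latency_s=0.0, valid=True)
                )
        return metrics_frame(rows)

    def test_identical_immortal_animals_give_their_trajectory(self):
        m = self.metrics_for({0: 5.0, 1: 5.0})
        recs = [WormRecord(0, death_time_h=1000.0), WormRecord(1, death_time_h=1000.0)]
        out = survivor_population_curve(m, recs)
        assert (out["stimulated"] == 5.0).all()
        assert (out["n_alive"] == 2).all()

    def test_curve_steps_when_one_animal_dies(self):
        m = self.metrics_for({0: 2.0, 1: 4.0})
        recs = [WormRecord(0, death_time_h=20.0), WormRecord(1, death_time_h=1000.0)]
        out = survivor_population_curve(m, recs)
        # epochs at 0 and 12 h include both (mean 3), later epochs only well 1
        assert out.loc[out["time_h"] == 0.0, "stimulated"].iloc[0] == 3.0
        assert out.loc[out["time_h"] == 24.0, "stimulated"].iloc[0] == 4.0

    def test_censored_animals_never_contribute(self):
        m = self.metrics_for({0: 2.0, 1: 100.0})
        recs = [
            WormRecord(0, death_time_h=1000.0),
            WormRecord(1, censored=True, censor_reason="zero_from_day2", censor_time_h=0.0),
        ]
        out = survivor_population_curve(m, recs)
        assert (out["stimulated"] == 2.0).all()


def test_epoch_metrics_table_marks_invalid_epochs(standard_schedule):
    # trace only covers epoch 0; epochs 1-3 lack windows -> invalid rows
    t60 = trace60([3, 1], [0, 7])
    t5 = trace5(np.ones(177))
    tbl = epoch_metrics_table([t5], [t60], standard_schedule)
    assert len(tbl) == 4
    assert tbl.loc[tbl["epoch_index"] == 0, "valid"].iloc[0]
    assert not tbl.loc[tbl["epoch_index"] == 2, "valid"].iloc[0]
    assert np.isnan(tbl.loc[tbl["epoch_index"] == 2, "stimulated"].iloc[0])
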