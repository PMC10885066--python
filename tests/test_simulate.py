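"""Schedules, setpoint dynamics and the nested protocol simulator."""

import math

import numpy as np
import pytest

import somnostat as sm
from somnostat.schedule import Interval


def sleep_mask(traj: sm.Trajectory) -> np.ndarray:
    return np.isin(traj.state, [sm.NREM, sm.REM])


class TestScheduleBuilders:
    def test_allnight_default_structure(self, night_schedule):
        ivs = night_schedule.intervals
        assert ivs[0].state == sm.WAKE and (ivs[0].start, ivs[0].end) == (7.0, 23.0)
        sleep = [iv for iv in ivs[1:]]
        assert [iv.state for iv in sleep] == [sm.NREM, sm.REM] * 5
        assert night_schedule.end == pytest.approx(30.5)
        # REM episodes lengthen across the night
        rems = [iv.duration for iv in sleep if iv.state == sm.REM]
        assert all(b > a for a, b in zip(rems, rems[1:]))
        assert sum(iv.duration for iv in sleep) == pytest.approx(7.5)

    def test_allnight_explicit_cycles(self):
        sched = sm.build_allnight_schedule(n_cycles=5, nrem_minutes=60, rem_minutes=30)
        sleep = sched.intervals[1:]
        assert len(sleep) == 10
        assert sched.end == pytest.approx(30.5)

    def test_relay_mode_window_only(self):
        sched = sm.build_allnight_schedule(mode="relay")
        assert [iv.state for iv in sched.intervals] == [sm.WAKE, sm.SLEEP_WINDOW]
        assert sched.mode == "relay"

    def test_overflowing_cycles_rejected(self):
        with pytest.raises(sm.ConfigurationError):
            sm.build_allnight_schedule(n_cycles=20, nrem_minutes=65, rem_minutes=25)

    @pytest.mark.parametrize("group, first", [("SD", 30.0), ("SR", 31.0)])
    def test_nap_protocols(self, group, first):
        sched = sm.build_nap_schedule(group)
        naps = [iv for iv in sched.intervals
                if iv.state == sm.NREM and iv.start >= first - 1e-9]
        assert len(naps) == 12
        onsets = [iv.start for iv in naps]
        assert onsets == pytest.approx([first + 2.0 * i for i in range(12)])
        assert all(iv.duration == pytest.approx(1 / 3) for iv in naps)

    def test_sd_naps_lead_sr_naps_by_one_hour(self):
        sd = [iv.start for iv in sm.build_nap_schedule("SD").intervals
              if iv.state == sm.NREM]
        sr = [iv.start for iv in sm.build_nap_schedule("SR").intervals
              if iv.state == sm.NREM and iv.start >= 31.0]
        assert np.allclose(np.array(sd) - np.array(sr), -1.0)

    def test_sr_night_is_seven_hours(self):
        sched = sm.build_nap_schedule("SR")
        night = [iv for iv in sched.intervals
                 if iv.state in (sm.NREM, sm.REM) and iv.end <= 30.0 + 1e-9]
        assert sum(iv.duration for iv in night) == pytest.approx(7.0)

    def test_schedule_json_roundtrip(self, night_schedule):
        again = sm.Schedule.from_json(night_schedule.to_json())
        assert again == night_schedule
        sr = sm.build_nap_schedule("SR")
        assert sm.Schedule.from_json(sr.to_json()).s_resets == sr.s_resets

    def test_non_contiguous_intervals_rejected(self):
        with pytest.raises(sm.ConfigurationError):
            sm.Schedule((Interval(0, 1, sm.WAKE), Interval(2, 3, sm.NREM)))


class TestSetpointTrace:
    def test_starts_at_onset_value(self):
        ivs = [Interval(23.0, 24.5, sm.NREM)]
        df = sm.setpoint_trace(1.10, schedule=ivs)
        assert df.s_u.iloc[0] == pytest.approx(1.10, abs=1e-12)

    def test_one_time_constant_of_cumulative_nrem(self):
        # 0.70 + 0.40/e after 1.40 h of NREM
        ivs = [Interval(23.0, 24.4, sm.NREM)]
        df = sm.setpoint_trace(1.10, schedule=ivs)
        assert df.s_u.iloc[-1] == pytest.approx(0.70 + 0.40 / math.e, abs=1e-9)
        assert df.s_u.iloc[-1] == pytest.approx(0.8472, abs=5e-5)

    def test_frozen_during_rem(self):
        ivs = [Interval(23.0, 24.0, sm.NREM), Interval(24.0, 24.5, sm.REM),
               Interval(24.5, 25.5, sm.NREM)]
        df = sm.setpoint_trace(1.10, schedule=ivs)
        rem = df[(df.time_h >= 24.0) & (df.time_h <= 24.5)]
        assert rem.s_u.nunique() == 1
        # and the decay resumes afterwards
        assert df.s_u.iloc[-1] < rem.s_u.iloc[0]

    def test_monotone_non_increasing(self, night_schedule):
        ivs = [iv for iv in night_schedule.intervals if iv.state != sm.WAKE]
        df = sm.setpoint_trace(1.10, schedule=ivs)
        assert np.all(np.diff(df.s_u) <= 1e-12)

    def test_frozen_after_fourth_cycle(self, night_schedule, params):
        traj = sm.simulate_protocol(night_schedule, params)
        # everything from the end of the 4th NREM phase onwards is constant
        nrem4_end = [iv for iv in traj.intervals if iv.state == sm.NREM][3].end
        tail = traj.s_u[(traj.time_h >= nrem4_end) & sleep_mask(traj)]
        assert np.ptp(tail) < 1e-12

    def test_onset_below_baseline_rejected(self):
        with pytest.raises(sm.ConfigurationError):
            sm.setpoint_trace(0.5, schedule=[Interval(0, 1, sm.NREM)])


class TestSleepEpisode:
    def test_relay_steady_cycle_durations(self, params):
        # with the setpoint at its baseline 0.70, NREM lasts
        # t_b*ln((s_u-s_b)/(s_u-s_d)) and REM t_d*ln((s_d-s_l)/(s_b-s_l))
        coupling = sm.SetpointCoupling()
        traj = sm.simulate_sleep_episode(
            0.70 + 1e-12, params.s, coupling, (0.0, 6.0), dt=1e-3
        )
        nrem = [iv for iv in traj.intervals if iv.state == sm.NREM]
        rem = [iv for iv in traj.intervals if iv.state == sm.REM]
        assert nrem[1].duration == pytest.approx(0.1615, abs=2e-4)
        assert rem[0].duration == pytest.approx(0.9501, abs=1e-4)
        rem_durs = [iv.duration for iv in rem[:-1]]
        assert np.ptp(rem_durs) < 1e-9  # identical every cycle

    def test_relay_switches_hit_thresholds_exactly(self, params, s_onset_16h):
        traj = sm.simulate_sleep_episode(s_onset_16h, params.s, schedule=(23.0, 30.5))
        for iv in traj.intervals[:-1]:
            if iv.state == sm.NREM:
                assert iv.s_exit == pytest.approx(params.s.D, abs=1e-10)
            else:
                assert iv.s_exit == pytest.approx(params.s.B, abs=1e-10)

    def test_relay_unreachable_threshold(self, params):
        bad = sm.SetpointCoupling(s_u_baseline=0.70)
        with pytest.raises(sm.UnreachableThresholdError):
            sm.simulate_sleep_episode(0.21, params.s, bad, (0.0, 2.0))

    def test_scheduled_zero_rem_is_pure_buildup(self, params):
        # with no REM intervals, s is the single compound buildup toward
        # the decaying setpoint (no oscillation, no phase boundaries)
        ivs = [Interval(23.0, 26.0, sm.NREM)]
        traj = sm.simulate_sleep_episode(1.10, params.s, schedule=ivs)
        assert all(iv.state == sm.NREM for iv in traj.intervals)
        d = traj.time_h - 23.0
        su = 0.70 + (1.10 - 0.70) * np.exp(-d / 1.40)
        expected = su - (su - params.s.B) * np.exp(-d / params.s.T_build)
        assert np.max(np.abs(traj.s - expected)) < 1e-12

    def test_relay_matches_dense_grid_reference(self, params, s_onset_16h):
        """Analytic switch solving agrees with an independent dense-grid
        forward simulation whose threshold crossings are located by linear
        interpolation between grid samples."""
        coupling = sm.SetpointCoupling()
        sp = params.s
        dt = 1e-4
        t0, t1 = 23.0, 30.5
        n = int(round((t1 - t0) / dt))
        ts = t0 + np.arange(n + 1) * dt
        s_ref = np.empty(n + 1)
        state = sm.NREM
        clock = 0.0  # cumulative NREM hours
        cycle = 1
        frozen = False
        su_frozen = np.nan
        seg_start, s_entry = t0, sp.B

        def value(t, d):
            if frozen:
                su = su_frozen
            else:
                adv = d if state == sm.NREM else 0.0
                su = 0.70 + (s_onset_16h - 0.70) * math.exp(
                    -(clock + adv) / coupling.T_set
                )
            if state == sm.NREM:
                return su, su - (su - s_entry) * math.exp(-d / sp.T_build)
            return su, sp.L + (s_entry - sp.L) * math.exp(-d / sp.T_decay)

        s_prev = s_entry
        for i, t in enumerate(ts):
            su, s = value(t, t - seg_start)
            thr = sp.D if state == sm.NREM else sp.B
            crossed = s >= thr if state == sm.NREM else s <= thr
            if crossed and i > 0:
                frac = (thr - s_prev) / (s - s_prev)
                t_sw = (t - dt) + frac * dt
                if state == sm.NREM:
                    if not frozen:
                        clock += t_sw - seg_start
                        if cycle >= coupling.freeze_after_cycle:
                            su_frozen = 0.70 + (s_onset_16h - 0.70) * math.exp(
                                -clock / coupling.T_set
                            )
                            frozen = True
                    state = sm.REM
                else:
                    state = sm.NREM
                    cycle += 1
                seg_start, s_entry = t_sw, thr
                su, s = value(t, t - seg_start)
            s_ref[i] = s
            s_prev = s
        traj = sm.simulate_sleep_episode(s_onset_16h, sp, coupling, (t0, t1), dt=dt)
        assert np.max(np.abs(traj.s - s_ref)) < 1e-3


class TestProtocol:
    def test_S_at_sleep_onset(self, night_traj):
        i = np.argmin(np.abs(night_traj.time_h - 23.0))
        assert night_traj.S[i] == pytest.approx(1.0960, abs=5e-5)
        assert round(float(night_traj.S[i]), 2) == 1.10

    def test_sd_S_at_first_nap(self, params):
        traj = sm.simulate_protocol(sm.build_nap_schedule("SD"), params)
        assert traj.episodes[0][1] == pytest.approx(1.2347, abs=5e-5)

    def test_sr_morning_reset(self, params):
        traj = sm.simulate_protocol(sm.build_nap_schedule("SR"), params)
        nap1_onset, nap1_S = [e for e in traj.episodes if e[0] >= 31.0 - 1e-9][0]
        assert nap1_onset == pytest.approx(31.0)
        assert nap1_S == pytest.approx(0.3243, abs=5e-5)

    def test_wake_only_schedule_has_no_ultradian_process(self, params):
        sched = sm.Schedule((Interval(7.0, 23.0, sm.WAKE),))
        traj = sm.simulate_protocol(sched, params)
        assert np.all(np.isnan(traj.s))
        assert np.all(np.isnan(traj.s_u))
        assert traj.episodes == []

    def test_continuity_at_every_boundary(self, params):
        for sched in (
            sm.build_allnight_schedule(),
            sm.build_allnight_schedule(mode="relay"),
            sm.build_nap_schedule("SD"),
            sm.build_nap_schedule("SR"),
        ):
            traj = sm.simulate_protocol(sched, params)
            for a, b in zip(traj.intervals, traj.intervals[1:]):
                if any(abs(b.start - t) < 1e-9 for t in sched.s_resets):
                    continue  # prescribed S restart, discontinuous by design
                for fa, fb in (
                    (a.su_exit, b.su_entry), (a.s_exit, b.s_entry),
                    (a.S_exit, b.S_entry),
                ):
                    if np.isfinite(fa) and np.isfinite(fb):
                        assert abs(fa - fb) < 1e-9

    def test_setpoint_is_process_S_during_sleep(self, night_traj):
        sel = sleep_mask(night_traj)
        assert np.array_equal(night_traj.S[sel], night_traj.s_u[sel])

    def test_prior_wake_monotonically_raises_onset_peak_and_slope(self, params):
        onsets, peaks, slopes = [], [], []
        for wake_h in (2, 5, 8, 11, 14, 17, 20, 23):
            sched = sm.build_allnight_schedule(t1=23.0 - wake_h)
            traj = sm.simulate_protocol(sched, params)
            onsets.append(traj.episodes[0][1])
            c1 = sm.summarize_cycles(traj)[0]
            peaks.append(c1.amplitude + np.nanmin(
                traj.s[(traj.time_h >= c1.start) & (traj.time_h < c1.end)]
            ))
            slopes.append(
                sm.buildup_steepness(traj, 23.0, params.s).analytic_slope
            )
        for series in (onsets, peaks, slopes):
            assert all(b > a for a, b in zip(series, series[1:]))

    def test_sampling_grid_and_states(self, night_traj, night_schedule):
        assert night_traj.time_h[0] == pytest.approx(7.0)
        assert night_traj.time_h[-1] == pytest.approx(30.5)
        assert np.allclose(np.diff(night_traj.time_h), 1 / 60)
        # label run lengths match the scheduled block lengths
        changes = np.nonzero(night_traj.state[1:] != night_traj.state[:-1])[0] + 1
        bounds = night_traj.time_h[changes]
        expected = [iv.start for iv in night_schedule.intervals[1:]]
        assert np.allclose(bounds, expected, atol=1e-9)

    def test_trajectory_frame_roundtrip(self, night_traj):
        df = night_traj.to_frame()
        again = sm.Trajectory.from_frame(df)
        assert np.allclose(again.S, night_traj.S, equal_nan=True)
        assert [iv.state for iv in again.intervals] == [
            iv.state for iv in night_traj.intervals
        ]
        assert len(again.episodes) == 1
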