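"""Trajectory simulation, threshold switching and the scenario protocols."""

import math

import numpy as np
import pytest

import srsleep as sr
from srsleep.params import AttenuationProfile, RParams, SCParams, SParams


class TestPrescribed:
    def test_defining_relation_machine_precision(self, baseline_traj):
        assert np.array_equal(baseline_traj.P, baseline_traj.S * baseline_traj.R)

    def test_s_bounded_and_continuous(self, baseline_traj, sp):
        S = baseline_traj.S
        assert np.all(S >= sp.lower_asymptote - 1e-9)
        assert np.all(S <= sp.upper_asymptote + 1e-9)
        # max possible slope bounds the per-sample jump
        max_slope = max(1.0 / sp.tau_rise, 1.0 / sp.tau_fall)
        assert np.max(np.abs(np.diff(S))) <= max_slope * baseline_traj.dt * 1.01

    def test_state_matches_schedule(self, baseline_traj, baseline_sched):
        assert np.array_equal(
            baseline_traj.state, baseline_sched.is_sleep(baseline_traj.t)
        )

    def test_dt_refinement_invariance(self, baseline_sched, sp, rp):
        coarse = sr.simulate_prescribed(baseline_sched, sp, rp, dt=0.1)
        fine = sr.simulate_prescribed(baseline_sched, sp, rp, dt=0.05)
        assert np.allclose(coarse.P, fine.P[::2], atol=1e-6)

    def test_zero_attenuation_makes_p_proportional_to_s(self, baseline_sched, sp, rp):
        att = AttenuationProfile(((0.0, 1.0), (0.0 + 1e-9, 0.0)), origin_h=-1.0, day_hours=1.0)
        traj = sr.simulate_prescribed(baseline_sched, sp, rp, attenuation=att, dt=0.1)
        ratio = traj.P / traj.S
        assert np.ptp(ratio[10:]) == pytest.approx(0.0, abs=1e-9)

    def test_coarse_dt_error_names_episode(self, sp, rp):
        sched = sr.build_ultrashort(total=1.0)
        with pytest.raises(ValueError, match="episode"):
            sr.simulate_prescribed(sched, sp, rp, dt=0.1)

    def test_csv_round_trip_columns(self, tmp_path, baseline_traj):
        path = tmp_path / "traj.csv"
        baseline_traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["t_hours", "clock_hours", "state", "S", "R", "P"]
        assert np.allclose(df.P, baseline_traj.P, atol=1e-6)


class TestThresholdSwitching:
    def test_constant_thresholds_match_closed_forms(self, sp):
        scp = SCParams(h_mean=0.6, h_amp=0.0, l_mean=0.2, l_amp=0.0)
        _, rec = sr.simulate_threshold_switching(sp, scp, t_end=96.0, dt=0.1, s0=0.3)
        wake = sp.tau_rise * math.log((1 - 0.2) / (1 - 0.6))
        sleep = sp.tau_fall * math.log((0.6 - 0.05) / (0.2 - 0.05))
        assert wake == pytest.approx(12.62, abs=0.01)
        assert sleep == pytest.approx(5.46, abs=0.01)
        intervals = np.diff(rec.times)
        expected = [sleep if k == "offset" else wake for k in rec.kinds[1:]]
        assert np.allclose(intervals, expected, atol=1e-3)

    def test_degenerate_sinusoid_equals_constant_case(self, sp):
        flat = SCParams(h_mean=0.6, h_amp=0.0, l_mean=0.2, l_amp=0.0)
        sine0 = SCParams(h_mean=0.6, h_amp=0.0, l_mean=0.2, l_amp=0.0, phase=5.0)
        _, r1 = sr.simulate_threshold_switching(sp, flat, 72.0, 0.1, s0=0.3)
        _, r2 = sr.simulate_threshold_switching(sp, sine0, 72.0, 0.1, s0=0.3)
        assert np.allclose(r1.times, r2.times, atol=1e-9)

    def test_onsets_and_offsets_alternate(self, sp, defaults):
        _, rec = sr.simulate_threshold_switching(sp, defaults["sc_process"], 96.0, 0.1, s0=0.3)
        kinds = rec.kinds
        assert len(kinds) >= 4
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_trapped_wake_flagged(self):
        # asymptote below H: S can never trigger sleep onset
        p = SParams(upper_asymptote=0.5, s_init=0.3)
        scp = SCParams(h_mean=0.8, h_amp=0.0, l_mean=0.2, l_amp=0.0)
        _, rec = sr.simulate_threshold_switching(p, scp, 48.0, 0.1, s0=0.3)
        assert rec.trapped and rec.onsets == []

    def test_sinusoidal_run_switch_levels(self, sp, defaults):
        traj, rec = sr.simulate_threshold_switching(sp, defaults["sc_process"], 96.0, 0.05, s0=0.3)
        scp = defaults["sc_process"]
        for t, kind in zip(rec.times, rec.kinds):
            clock = (traj.origin_clock + t) % 24.0
            level = float(scp.h_at(clock) if kind == "onset" else scp.l_at(clock))
            assert traj.s_at(t) == pytest.approx(level, abs=2e-3)


class TestNapScenario:
    def test_immediate_mode_lowers_night_propensity_pointwise(self, sp, rp):
        res = sr.scenario_nap("immediate", sp, rp, dt=0.1)
        m = (res.baseline.t >= 32.0) & (res.baseline.t <= 48.0)  # nap end -> wake-up
        assert np.all(res.nap.P[m] <= res.baseline.P[m] + 1e-12)
        night = (res.baseline.t >= 40.0) & (res.baseline.t <= 48.0)
        assert np.all(res.nap.P[night] < res.baseline.P[night])

    def test_delayed_mode_postpones_onset(self, sp, rp):
        res = sr.scenario_nap("delayed", sp, rp, dt=0.1)
        assert res.onset_time is not None and res.onset_time > 40.0
        assert res.nap.p_at(res.onset_time) >= res.p_ref - 1e-9
        night = [e for e in res.schedule_nap.episodes if e.start == res.onset_time]
        assert night and night[0].end == pytest.approx(48.0)  # rise time fixed

    def test_skipped_nap_reproduces_baseline(self, sp, rp):
        res = sr.scenario_nap("immediate", sp, rp, dt=0.1, nap_hours=0.0)
        assert np.array_equal(res.nap.P, res.baseline.P)


class TestSweepShift:
    def test_zero_delta_reproduces_baseline_features(self, sp, rp, cfg, baseline_features):
        pts = sr.sweep_shift([0.0], "delay", sp, rp, 0.1, cfg)
        fs = pts[0].features
        assert fs.anz_time == pytest.approx(baseline_features.anz_time)
        assert fs.wmz_time == pytest.approx(baseline_features.wmz_time)
        assert fs.nocturnal_peak_value == pytest.approx(
            baseline_features.nocturnal_peak_value
        )

    def test_delay_prominence_non_increasing(self, sp, rp, cfg):
        pts = sr.sweep_shift(list(range(7)), "delay", sp, rp, 0.1, cfg)
        proms = [p.features.anz_prominence for p in pts]
        assert all(a >= b - 1e-12 for a, b in zip(proms, proms[1:]))

    def test_advance_makes_peaks_comparable(self, sp, rp, cfg):
        pts = sr.sweep_shift([2.0, 3.0, 4.0], "advance", sp, rp, 0.1, cfg)
        for p in pts:
            ratio = sr.peak_ratio(p.features)
            assert ratio is not None and 0.8 <= ratio <= 1.25

    def test_unsorted_deltas_rejected(self, sp, rp):
        with pytest.raises(ValueError):
            sr.sweep_shift([3.0, 1.0], "delay", sp, rp)


class TestFdScenario:
    def test_restricted_arm_loses_anz_at_fd2(self, sp, rp, cfg):
        res = sr.scenario_fd((1, 5), 7, dt=0.1, s_params=sp, r_params=rp)
        assert res.first_day_without_anz(cfg) == 2

    def test_habitual_arm_keeps_wmz_every_day(self, sp, rp, cfg):
        res = sr.scenario_fd((1, 2), 7, dt=0.1, s_params=sp, r_params=rp)
        assert all(fs.wmz_present for fs in res.day_features(cfg))

    def test_restricted_arm_loses_wmz_by_fd7(self, sp, rp, cfg):
        res = sr.scenario_fd((1, 5), 7, dt=0.1, s_params=sp, r_params=rp)
        assert not res.day_features(cfg)[6].wmz_present

    def test_unit_end_scale_leaves_r_at_baseline(self, sp, rp):
        res = sr.scenario_fd((1, 5), 3, attenuation_end_scale=1.0, dt=0.1,
                             s_params=sp, r_params=rp)
        expected = sr.r_value(res.trajectory.clock_t, rp)
        assert np.allclose(res.trajectory.R, expected, atol=1e-12)

    def test_habitual_arm_never_attenuated(self, sp, rp):
        res = sr.scenario_fd((1, 2), 3, dt=0.1, s_params=sp, r_params=rp)
        assert res.attenuation is None


class TestNarcolepsy:
    def test_no_wake_maintenance_zone(self, sp, cfg):
        res = sr.scenario_narcolepsy(dt=0.1, s_params=sp)
        fs = sr.classify_window(res.trajectory, res.schedule, 30.0, 24.0, cfg)
        assert not fs.wmz_present

    def test_r_range_small(self, sp):
        res = sr.scenario_narcolepsy(dt=0.1, s_params=sp)
        assert np.ptp(res.trajectory.R) < 0.15

    def test_nightly_s_stays_below_entrained_maximum(self, sp, baseline_traj):
        res = sr.scenario_narcolepsy(dt=0.1, s_params=sp)
        narc_day2 = (res.trajectory.t >= 24.0) & (res.trajectory.t < 48.0)
        base_day2 = (baseline_traj.t >= 24.0) & (baseline_traj.t < 48.0)
        assert res.trajectory.S[narc_day2].max() < baseline_traj.S[base_day2].max()

    def test_pre_nap_propensity_exceeds_baseline_daytime_max(
        self, sp, baseline_traj, baseline_sched
    ):
        res = sr.scenario_narcolepsy(dt=0.1, s_params=sp)
        day = (baseline_traj.t >= 24.0) & (baseline_traj.t < 48.0)
        wake = day & ~baseline_traj.state
        base_day_max = baseline_traj.P[wake].max()
        for clock in (10.0, 14.0, 17.5):
            assert res.trajectory.p_at(24.0 + clock - 0.1) > base_day_max

    def test_large_amplitude_rejected(self, sp):
        with pytest.raises(ValueError):
            sr.scenario_narcolepsy(
                r_ceiling_params=RParams(floor=0.5, amplitude=0.4), s_params=sp
            )
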