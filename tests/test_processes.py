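"""Closed-form process dynamics against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import srsleep as sr
from srsleep.params import RParams, SCParams, SParams
from srsleep.processes import s_fall, s_rise


def euler_s(s0, hours, state, params, dt=1e-4):
    """Fine-step Euler integration of dS/dt, the independent oracle."""
    s = s0
    n = int(round(hours / dt))
    for _ in range(n):
        if state == "wake":
            s += dt * (params.upper_asymptote - s) / params.tau_rise
        else:
            s += -dt * (s - params.lower_asymptote) / params.tau_fall
    return s


class TestSStep:
    def test_upper_asymptote_is_fixed_point(self, sp):
        assert sr.s_step(sp.upper_asymptote, 5.0, "wake", sp) == pytest.approx(
            sp.upper_asymptote
        )

    @pytest.mark.parametrize(
        "s0,hours,state,expected",
        [
            (0.2, 16.0, "wake", 0.6679),
            (0.6679, 8.0, "sleep", 0.1420),
        ],
    )
    def test_matches_ode_oracle(self, sp, s0, hours, state, expected):
        analytic = sr.s_step(s0, hours, state, sp)
        oracle = euler_s(s0, hours, state, sp)
        assert analytic == pytest.approx(oracle, abs=1e-4)
        assert analytic == pytest.approx(expected, abs=5e-4)

    def test_oracle_agreement_along_trajectory(self, sp):
        # one full day of wake then sleep, checked hourly at fine-step tolerance
        s = 0.2
        for h in range(16):
            a = sr.s_step(s, 1.0, "wake", sp)
            o = euler_s(s, 1.0, "wake", sp)
            assert abs(a - o) <= 1e-5
            s = a
        for h in range(8):
            a = sr.s_step(s, 1.0, "sleep", sp)
            o = euler_s(s, 1.0, "sleep", sp)
            assert abs(a - o) <= 1e-5
            s = a

    def test_domain_errors(self, sp):
        with pytest.raises(ValueError):
            sr.s_step(1.5, 1.0, "wake", sp)
        with pytest.raises(ValueError):
            sr.s_step(0.5, -1.0, "wake", sp)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        s0=st.floats(0.05, 1.0),
        d1=st.floats(0.0, 10.0),
        d2=st.floats(0.0, 10.0),
        state=st.sampled_from(["wake", "sleep"]),
    )
    def test_semigroup_and_bounds(self, s0, d1, d2, state):
        p = SParams()
        one = sr.s_step(s0, d1 + d2, state, p)
        two = sr.s_step(sr.s_step(s0, d1, state, p), d2, state, p)
        assert one == pytest.approx(two, abs=1e-12)
        assert p.lower_asymptote - 1e-12 <= one <= p.upper_asymptote + 1e-12


class TestRValue:
    def test_acrophase_gives_maximum(self, rp):
        assert sr.r_value(rp.acrophase, rp) == pytest.approx(rp.floor + rp.amplitude)
        grid = np.arange(0, 24, 0.01)
        assert np.max(sr.r_value(grid, rp)) <= rp.floor + rp.amplitude + 1e-12

    def test_antiphase_reaches_floor_for_symmetric_cosine(self):
        p = RParams(floor=0.05, amplitude=0.9, acrophase=8.0)
        assert sr.r_value(20.0, p) == pytest.approx(p.floor)

    def test_zero_scale_flattens_to_mesor(self, rp):
        grid = np.arange(0, 24, 0.25)
        flat = sr.r_value(grid, rp, amplitude_scale=0.0)
        assert np.ptp(flat) == pytest.approx(0.0, abs=1e-12)
        assert flat[0] == pytest.approx(rp.mesor)

    def test_periodicity_exact(self, rp):
        t = np.linspace(0, 24, 97)
        assert np.allclose(sr.r_value(t, rp), sr.r_value(t + 24.0, rp), atol=0, rtol=0)

    def test_strictly_positive_at_any_scale(self, rp):
        grid = np.arange(0, 24, 0.05)
        for scale in (0.0, 0.3, 1.0):
            assert np.all(sr.r_value(grid, rp, scale) > 0)

    def test_skew_preserves_max_and_min_levels(self, rp):
        grid = np.arange(0, 24, 0.001)
        vals = sr.r_value(grid, rp)
        assert np.max(vals) == pytest.approx(rp.floor + rp.amplitude, abs=1e-6)
        assert np.min(vals) == pytest.approx(rp.floor, abs=1e-5)


class TestPropensity:
    def test_product_and_errors(self):
        assert sr.propensity(0.5, 0.4) == pytest.approx(0.2)
        assert sr.propensity(1.0, 1.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            sr.propensity(0.0, 0.5)
        with pytest.raises(ValueError):
            sr.propensity(0.5, -0.1)

    def test_monotone_in_both_arguments(self):
        assert sr.propensity(0.7, 0.05) < sr.propensity(1.0, 0.95)


class TestThresholds:
    def test_flat_amplitudes_give_means(self):
        p = SCParams(h_amp=0.0, l_amp=0.0)
        h, l = sr.thresholds_hl(np.arange(0, 24, 1.0), p)
        assert np.allclose(h, p.h_mean) and np.allclose(l, p.l_mean)

    def test_phase_zero_crossing(self):
        p = SCParams()
        h, l = sr.thresholds_hl(p.phase, p)
        assert h == pytest.approx(p.h_mean) and l == pytest.approx(p.l_mean)

    def test_separation_positive_on_grid(self, defaults):
        p = defaults["sc_process"]
        grid = np.arange(0, 24, 0.05)
        h, l = sr.thresholds_hl(grid, p)
        assert np.min(h - l) > 0

    def test_crossing_config_rejected(self):
        with pytest.raises(ValueError):
            SCParams(h_mean=0.5, h_amp=0.0, l_mean=0.45, l_amp=0.2)

    def test_skewed_lower_differs_but_means_match(self):
        plain = SCParams()
        skewed = SCParams(skew_l=True)
        grid = np.arange(0, 24, 0.5)
        assert not np.allclose(plain.l_at(grid), skewed.l_at(grid))
        assert np.mean(plain.l_at(np.arange(0, 24, 0.01))) == pytest.approx(
            np.mean(skewed.l_at(np.arange(0, 24, 0.01))), abs=1e-3
        )


class TestRemLatencyToR:
    def test_minmax_endpoints(self):
        res = sr.rem_latency_to_r([(2.0, 60.0), (14.0, 120.0)], offset_min=10.0, floor=0.05)
        assert res.r == pytest.approx([1.0, 0.05])

    def test_three_point_rescale_against_hand_computation(self):
        # raw = 1/L at c=0: (1/30, 1/60, 1/120); min-max onto [0, 1]
        res = sr.rem_latency_to_r(
            [(1.0, 30.0), (9.0, 60.0), (17.0, 120.0)], offset_min=0.0, floor=0.0
        )
        expected = [1.0, (1 / 60 - 1 / 120) / (1 / 30 - 1 / 120), 0.0]
        assert res.r == pytest.approx(expected)

    def test_halving_latencies_preserves_rank_order(self):
        pairs = [(0.0, 45.0), (6.0, 90.0), (12.0, 150.0), (18.0, 70.0)]
        a = sr.rem_latency_to_r(pairs).r
        b = sr.rem_latency_to_r([(c, l / 2) for c, l in pairs]).r
        assert list(np.argsort(a)) == list(np.argsort(b))

    def test_identical_latencies_flat_with_flag(self):
        res = sr.rem_latency_to_r([(0.0, 80.0), (12.0, 80.0)], floor=0.05)
        assert res.flat_input
        assert res.r == pytest.approx([(0.05 + 1) / 2] * 2)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        lats=st.lists(st.floats(5.0, 400.0), min_size=3, max_size=12, unique=True)
    )
    def test_order_reversing(self, lats):
        pairs = [(i * 1.7 % 24, l) for i, l in enumerate(lats)]
        res = sr.rem_latency_to_r(pairs)
        by_latency = res.r[np.argsort([l for _, l in pairs])]
        assert np.all(np.diff(by_latency) <= 1e-12)  # longer latency, lower drive

    def test_calibrated_mode_inverts_latency_map(self, lmap):
        lats = np.array([60.0, 90.0, 130.0, 180.0])
        pairs = list(zip([0.0, 6.0, 12.0, 18.0], lats))
        res = sr.rem_latency_to_r(pairs, mode="calibrated", latency_map=lmap)
        assert np.allclose(lmap.latency_of_r(res.r), lats, atol=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sr.rem_latency_to_r([(0.0, -5.0), (12.0, 60.0)])
        with pytest.raises(ValueError):
            sr.rem_latency_to_r([(3.0, 60.0), (3.0, 90.0)])


def test_entrained_fixed_points_are_periodic(sp):
    s_low, s_high = sr.entrained_fixed_points(sp)
    assert s_rise(s_low, 16.0, sp) == pytest.approx(s_high)
    assert s_fall(s_high, 8.0, sp) == pytest.approx(s_low)


def test_param_invariants_rejected():
    with pytest.raises(ValueError):
        SParams(lower_asymptote=0.0)
    with pytest.raises(ValueError):
        SParams(tau_rise=-1.0)
    with pytest.raises(ValueError):
        RParams(floor=0.2, amplitude=0.9)
    with pytest.raises(ValueError):
        RParams(period=25.0)
    with pytest.raises(ValueError):
        RParams(shape_exponent=0.5)


def test_config_round_trip(tmp_path, defaults):
    path = tmp_path / "params.yaml"
    sr.save_params(defaults, path)
    loaded = sr.load_params(path)
    assert loaded["s_process"] == defaults["s_process"]
    assert loaded["r_process"] == defaults["r_process"]
    assert loaded["features"] == defaults["features"]
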