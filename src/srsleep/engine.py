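"""Trajectory simulation and the named scenario protocols.

Two modes exist.  In *prescribed* mode the sleep-wake pattern is given by a
:class:`~srsleep.schedules.Schedule` and S follows its closed-form saturating
exponentials segment by segment, so sampled values are independent of the
grid step.  In *threshold* mode (classic S-C model) the state switches when S
crosses the sinusoidal thresholds H and L; crossing times are refined by
root-finding inside the bracketing step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import features as _features
from .params import AttenuationProfile, FeatureConfig, RParams, SCParams, SParams, default_params
from .processes import entrained_fixed_points, r_value, s_fall, s_rise
from .schedules import (
    Schedule,
    SleepEpisode,
    build_entrained,
    build_fd,
    build_narcolepsy,
    insert_nap,
    shift_main_sleep,
)

__all__ = [
    "Trajectory",
    "SwitchRecord",
    "simulate_prescribed",
    "simulate_threshold_switching",
    "scenario_nap",
    "scenario_fd",
    "sweep_shift",
    "scenario_narcolepsy",
    "NapScenario",
    "FdScenario",
    "SweepPoint",
    "NarcolepsyScenario",
]


@dataclass
class Trajectory:
    """Uniformly sampled state and drive levels over a protocol."""

    dt: float
    t: np.ndarray
    clock_t: np.ndarray
    state: np.ndarray  # True where asleep
    S: np.ndarray
    R: np.ndarray
    P: np.ndarray
    origin_clock: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_hours": self.t,
                "clock_hours": self.clock_t,
                "state": np.where(self.state, "sleep", "wake"),
                "S": self.S,
                "R": self.R,
                "P": self.P,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    def p_at(self, t):
        return np.interp(t, self.t, self.P)

    def s_at(self, t):
        return np.interp(t, self.t, self.S)


def _grid(horizon: float, dt: float) -> np.ndarray:
    n = int(round(horizon / dt))
    if abs(n * dt - horizon) > 1e-6:
        n = int(math.floor(horizon / dt + 1e-9))
    return np.arange(n + 1) * dt


def simulate_prescribed(
    schedule: Schedule,
    s_params: SParams | None = None,
    r_params: RParams | None = None,
    attenuation: AttenuationProfile | None = None,
    dt: float = 0.1,
    s0: float | None = None,
) -> Trajectory:
    """Simulate S, R and P = S*R over a prescribed sleep-wake schedule.

    S is evaluated in closed form from the start of each wake/sleep segment,
    so refining ``dt`` leaves values at shared grid points unchanged.  ``s0``
    (or ``s_params.s_init``) defaults to the entrained-cycle fixed point at
    wake-up.
    """
    defaults = default_params()
    s_params = s_params or defaults["s_process"]
    r_params = r_params or defaults["r_process"]
    if dt <= 0:
        raise ValueError("dt must be positive")
    shortest = min((e.duration for e in schedule.episodes), default=np.inf)
    if dt > shortest / 2.0 + 1e-12:
        bad = min(schedule.episodes, key=lambda e: e.duration)
        raise ValueError(
            f"dt={dt} h too coarse for episode [{bad.start:.3f}, {bad.end:.3f}) "
            f"of {bad.duration:.3f} h; need dt <= duration/2"
        )
    if s0 is None:
        s0 = s_params.s_init
    if s0 is None:
        s0 = entrained_fixed_points(s_params)[0]

    t = _grid(schedule.horizon, dt)
    state = schedule.is_sleep(t)
    S = np.empty_like(t)

    bounds = sorted(
        {0.0, schedule.horizon}
        | {e.start for e in schedule.episodes}
        | {min(e.end, schedule.horizon) for e in schedule.episodes}
    )
    s_seg = float(s0)
    for a, b in zip(bounds, bounds[1:]):
        asleep = bool(schedule.is_sleep(np.array([(a + b) / 2.0]))[0])
        seg = (t >= a - 1e-9) & (t <= b + 1e-9)
        rel = t[seg] - a
        S[seg] = s_fall(s_seg, rel, s_params) if asleep else s_rise(s_seg, rel, s_params)
        s_seg = float(s_fall(s_seg, b - a, s_params) if asleep else s_rise(s_seg, b - a, s_params))

    scale = attenuation.scale_at_time(t) if attenuation is not None else 1.0
    clock = schedule.clock_at(t)
    R = r_value(clock, r_params, scale)
    P = S * R

    assert np.all(S >= s_params.lower_asymptote - 1e-9)
    assert np.all(S <= s_params.upper_asymptote + 1e-9)
    return Trajectory(dt, t, clock, state, S, np.asarray(R), P, schedule.origin_clock)


@dataclass
class SwitchRecord:
    """Threshold-crossing events of the classic S-C model."""

    times: list[float]
    kinds: list[str]  # "onset" | "offset", strictly alternating
    trapped: bool = False

    def __post_init__(self) -> None:
        for a, b in zip(self.kinds, self.kinds[1:]):
            if a == b:
                raise ValueError("onsets and offsets must alternate")

    @property
    def onsets(self) -> list[float]:
        return [t for t, k in zip(self.times, self.kinds) if k == "onset"]

    @property
    def offsets(self) -> list[float]:
        return [t for t, k in zip(self.times, self.kinds) if k == "offset"]


def simulate_threshold_switching(
    s_params: SParams | None = None,
    sc_params: SCParams | None = None,
    t_end: float = 96.0,
    dt: float = 0.1,
    initial_state: Literal["wake", "sleep"] = "wake",
    s0: float | None = None,
    origin_clock: float = 8.0,
) -> tuple[Trajectory, SwitchRecord]:
    """Classic two-process run: sleep onset at S >= H, awakening at S <= L.

    Crossings are bracketed on the sampling grid and refined with Brent's
    method on the analytic segment, so switch times do not depend on ``dt``
    beyond bracketing.  If S can never reach H during wake the run completes
    with zero onsets and the record's ``trapped`` flag set.
    """
    defaults = default_params()
    s_params = s_params or defaults["s_process"]
    sc_params = sc_params or defaults["sc_process"]
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = _grid(t_end, dt)
    n = t.size
    S = np.empty(n)
    state = np.zeros(n, dtype=bool)
    asleep = initial_state == "sleep"
    s = float(s0 if s0 is not None else (sc_params.l_mean + sc_params.h_mean) / 2.0)
    S[0] = s
    state[0] = asleep
    times: list[float] = []
    kinds: list[str] = []

    def h_at(tt):
        return float(sc_params.h_at((origin_clock + tt) % 24.0))

    def l_at(tt):
        return float(sc_params.l_at((origin_clock + tt) % 24.0))

    for i in range(n - 1):
        t0 = t[i]
        remaining = dt
        # at most a handful of switches can occur within one step
        for _ in range(4):
            step = lambda tau: (
                s_fall(s, tau, s_params) if asleep else s_rise(s, tau, s_params)
            )
            if asleep:
                f = lambda tau: float(step(tau)) - l_at(t0 + tau)
            else:
                f = lambda tau: h_at(t0 + tau) - float(step(tau))
            f0, f1 = f(0.0), f(remaining)
            if f0 <= 0.0:
                tau_x = 0.0
            elif f1 > 0.0:
                break  # no crossing in this step
            else:
                tau_x = brentq(f, 0.0, remaining, xtol=1e-10)
            s = float(step(tau_x))
            t0 = t0 + tau_x
            remaining = t[i + 1] - t0
            times.append(t0)
            kinds.append("offset" if asleep else "onset")
            asleep = not asleep
        s = float(s_fall(s, remaining, s_params) if asleep else s_rise(s, remaining, s_params))
        S[i + 1] = s
        state[i + 1] = asleep

    trapped = "onset" not in kinds
    clock = (origin_clock + t) % 24.0
    nan = np.full(n, np.nan)
    traj = Trajectory(dt, t, clock, state, S, nan, nan.copy(), origin_clock)
    return traj, SwitchRecord(times, kinds, trapped)


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class NapScenario:
    baseline: Trajectory
    nap: Trajectory
    onset_time: float | None  # hours since origin; None if never reached
    p_ref: float
    schedule_baseline: Schedule
    schedule_nap: Schedule
    warning: str | None = None


def scenario_nap(
    mode: Literal["immediate", "delayed"],
    s_params: SParams | None = None,
    r_params: RParams | None = None,
    dt: float = 0.1,
    nap_start_clock: float = 14.0,
    nap_hours: float = 2.0,
) -> NapScenario:
    """Effect of an afternoon nap on the subsequent night.

    Day 0 is an undisturbed entrained day, day 1 carries the nap.  In
    ``immediate`` mode night sleep starts at the habitual bedtime; in
    ``delayed`` mode sleep onset waits until propensity regains the baseline
    bedtime level (P_ref), with wake-up fixed at the habitual rise time.
    """
    base_sched = build_entrained(2)
    baseline = simulate_prescribed(base_sched, s_params, r_params, dt=dt)
    habitual_onset = base_sched.episodes[-1].start
    p_ref = float(baseline.p_at(habitual_onset))

    if nap_hours == 0.0:
        nap_sched = base_sched  # skipped nap
    else:
        nap_sched = insert_nap(base_sched, nap_start_clock, nap_hours, day=1)

    if mode == "immediate":
        nap_traj = simulate_prescribed(nap_sched, s_params, r_params, dt=dt)
        return NapScenario(baseline, nap_traj, habitual_onset, p_ref, base_sched, nap_sched)
    if mode != "delayed":
        raise ValueError("mode must be 'immediate' or 'delayed'")

    # remove the night episode, watch P climb back to the reference level
    open_eps = tuple(e for e in nap_sched.episodes if e.start != habitual_onset)
    open_sched = Schedule(nap_sched.origin_clock, open_eps, nap_sched.horizon)
    probe = simulate_prescribed(open_sched, s_params, r_params, dt=dt)
    after = probe.t >= habitual_onset - 1e-9
    hit = after & (probe.P >= p_ref - 1e-12)
    if not np.any(hit):
        return NapScenario(
            baseline, probe, None, p_ref, base_sched, open_sched,
            warning="propensity never regained the habitual onset level before wake-up",
        )
    onset = float(probe.t[hit][0])
    wake_t = habitual_onset + 8.0  # habitual rise time is kept fixed
    final = open_sched.with_episode(SleepEpisode(onset, wake_t - onset, "main"))
    nap_traj = simulate_prescribed(final, s_params, r_params, dt=dt)
    return NapScenario(baseline, nap_traj, onset, p_ref, base_sched, final)


@dataclass
class SweepPoint:
    delta: float
    trajectory: Trajectory
    features: "_features.FeatureSet"
    schedule: Schedule


def sweep_shift(
    deltas: Sequence[float],
    direction: Literal["delay", "advance"] = "delay",
    s_params: SParams | None = None,
    r_params: RParams | None = None,
    dt: float = 0.1,
    config: FeatureConfig | None = None,
) -> list[SweepPoint]:
    """Shift the preceding main sleep and classify next-day features.

    The nights *before* the analysis day are displaced by the shift while the
    analysis day itself ends in a night at the habitual bedtime — the
    question the sweep answers is how the phase of the *preceding* sleep
    period reshapes the following day's propensity landmarks.  The analysis
    window runs from 2 h before the (shifted) wake-up for 24 h.
    """
    if list(deltas) != sorted(deltas):
        raise ValueError("deltas must be sorted ascending")
    if any(d < 0 or d >= 12 for d in deltas):
        raise ValueError("each delta must lie in [0, 12)")
    sign = 1.0 if direction == "delay" else -1.0
    cfg = config or default_params()["features"]
    base = build_entrained(4)
    analysis_day_start = 48.0
    out = []
    for d in deltas:
        eps = []
        for e in base.episodes:
            if e.start < analysis_day_start:
                eps.append(SleepEpisode(e.start + sign * d, e.duration, e.kind))
            else:
                eps.append(e)
        sched = Schedule(base.origin_clock, tuple(sorted(eps, key=lambda e: e.start)), base.horizon)
        traj = simulate_prescribed(sched, s_params, r_params, dt=dt)
        # from 2 h before the shifted wake-up until the habitual next wake-up,
        # so the window never spills into the following morning
        window_start = analysis_day_start - 2.0 + sign * d
        window_hours = (analysis_day_start + 24.0) - window_start
        fs = _features.classify_window(traj, sched, window_start, window_hours, cfg)
        out.append(SweepPoint(float(d), traj, fs, sched))
    return out


@dataclass
class FdScenario:
    trajectory: Trajectory
    schedule: Schedule
    fd_start: float
    day_hours: float
    n_fd_days: int
    attenuation: AttenuationProfile | None
    sleep_to_wake: tuple[int, int]

    def day_features(self, config: FeatureConfig | None = None):
        """Feature classification per FD day (FD1 is the first 28-h day)."""
        cfg = config or default_params()["features"]
        return _features.fd_feature_table(
            self.trajectory, self.schedule, self.fd_start, self.day_hours,
            self.n_fd_days, cfg,
        )

    def first_day_without_anz(self, config: FeatureConfig | None = None) -> int | None:
        for d, fs in enumerate(self.day_features(config), start=1):
            if not fs.anz_present:
                return d
        return None


def scenario_fd(
    sleep_to_wake: tuple[int, int] = (1, 5),
    n_fd_days: int = 7,
    attenuation_end_scale: float | None = None,
    dt: float = 0.1,
    day_length: float = 28.0,
    adaptation_days: int = 2,
    s_params: SParams | None = None,
    r_params: RParams | None = None,
) -> FdScenario:
    """Forced-desynchrony run with progressive circadian attenuation of R.

    The severely restricted arm (sleep fraction < 1/3, e.g. 1:5) attenuates
    the circadian amplitude of R linearly from full at FD0 (start of the
    first FD day) to ``attenuation_end_scale`` at FD7; the habitual 1:2 arm
    keeps the full amplitude throughout.
    """
    defaults = default_params()
    if attenuation_end_scale is None:
        attenuation_end_scale = defaults["engine"]["attenuation_end_scale"]
    if not 0.0 <= attenuation_end_scale <= 1.0:
        raise ValueError("attenuation_end_scale must lie in [0, 1]")
    sched = build_fd(day_length, sleep_to_wake, n_fd_days, adaptation_days)
    fd_start = 24.0 * adaptation_days
    s, w = sleep_to_wake
    restricted = s / (s + w) < 1.0 / 3.0
    att = None
    if restricted:
        att = AttenuationProfile(
            day_scales=((0.0, 1.0), (float(n_fd_days), float(attenuation_end_scale))),
            origin_h=fd_start,
            day_hours=day_length,
        )
    traj = simulate_prescribed(sched, s_params, r_params, attenuation=att, dt=dt)
    return FdScenario(traj, sched, fd_start, day_length, n_fd_days, att, tuple(sleep_to_wake))


@dataclass
class NarcolepsyScenario:
    trajectory: Trajectory
    schedule: Schedule
    r_params: RParams


def scenario_narcolepsy(
    r_ceiling_params: RParams | None = None,
    narcolepsy_schedule: Schedule | None = None,
    dt: float = 0.1,
    s_params: SParams | None = None,
    n_days: int = 2,
) -> NarcolepsyScenario:
    """48-h polyphasic run with the ceiling-limited narcolepsy R drive.

    Sleep-onset REM implies extreme REM pressure: R sits near its ceiling
    with a small residual circadian amplitude, so the propensity profile is
    dominated by S and lacks a wake-maintenance zone.
    """
    defaults = default_params()
    if r_ceiling_params is None:
        healthy: RParams = defaults["r_process"]
        narc = defaults["narcolepsy_r"]
        r_ceiling_params = RParams(
            floor=narc["floor"],
            amplitude=narc["amplitude"],
            acrophase=healthy.acrophase,
            shape_exponent=healthy.shape_exponent,
            skew=healthy.skew,
        )
    if r_ceiling_params.amplitude > 0.15:
        raise ValueError("narcolepsy R amplitude must be <= 0.15 (ceiling effect)")
    sched = narcolepsy_schedule or build_narcolepsy(n_days)
    s_params = s_params or defaults["s_process"]
    # the run begins at a midnight sleep onset: start S at the entrained
    # bedtime fixed point and let the fragmented pattern take over
    s0 = entrained_fixed_points(s_params)[1]
    traj = simulate_prescribed(sched, s_params, r_ceiling_params, dt=dt, s0=s0)
    return NarcolepsyScenario(traj, sched, r_ceiling_params)
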