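"""Sleep-wake schedules for the simulated protocols.

A :class:`Schedule` is an ordered list of non-overlapping half-open sleep
episodes on a continuous hour axis starting at ``origin_clock`` (clock hours
of t = 0).  Constructors cover the entrained baseline, daytime naps, phase
shifts of the main sleep period, forced desynchrony (FD) days, the
ultra-short 7/13-min nap protocol, and a rule-generated narcolepsy actogram.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SleepEpisode",
    "Schedule",
    "build_entrained",
    "insert_nap",
    "shift_main_sleep",
    "build_fd",
    "build_ultrashort",
    "build_narcolepsy",
]


@dataclass(frozen=True)
class SleepEpisode:
    """Half-open sleep interval [start, start + duration) in hours since origin."""

    start: float
    duration: float
    kind: str = "main"  # main | nap | fd | ultrashort

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("episode start must be >= 0")
        if self.duration <= 0:
            raise ValueError("episode duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Schedule:
    origin_clock: float
    episodes: tuple[SleepEpisode, ...]
    horizon: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.origin_clock < 24.0:
            raise ValueError("origin_clock must lie in [0, 24)")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        eps = sorted(self.episodes, key=lambda e: e.start)
        if list(eps) != list(self.episodes):
            raise ValueError("episodes must be sorted by start")
        for a, b in zip(eps, eps[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(
                    f"episodes overlap: [{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
        for e in eps:
            if e.start >= self.horizon:
                raise ValueError("episode starts beyond the horizon")
            if e.end > self.horizon + 1e-9:
                raise ValueError("episode extends beyond the horizon (clip first)")

    # -- helpers ---------------------------------------------------------

    def clock_at(self, t):
        return (self.origin_clock + np.asarray(t, dtype=float)) % 24.0

    def is_sleep(self, t):
        """Vectorised half-open containment test (onset sample asleep)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for e in self.episodes:
            out |= (t >= e.start - 1e-12) & (t < e.end - 1e-12)
        return out

    def total_sleep(self, t0: float | None = None, t1: float | None = None) -> float:
        t0 = 0.0 if t0 is None else t0
        t1 = self.horizon if t1 is None else t1
        return float(
            sum(max(0.0, min(e.end, t1) - max(e.start, t0)) for e in self.episodes)
        )

    def with_episode(self, episode: SleepEpisode) -> "Schedule":
        if episode.end > self.horizon:
            episode = replace(episode, duration=self.horizon - episode.start)
        eps = tuple(sorted(self.episodes + (episode,), key=lambda e: e.start))
        return Schedule(self.origin_clock, eps, self.horizon)

    # -- serialisation ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# origin_clock={self.origin_clock:.6f} horizon={self.horizon:.6f}\n")
            fh.write("start_hours,duration_hours,kind\n")
            for e in self.episodes:
                fh.write(f"{e.start:.6f},{e.duration:.6f},{e.kind}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Schedule":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                kv.split("=") for kv in header.lstrip("# ").strip().split() if "=" in kv
            )
            df = pd.read_csv(fh)
        episodes = tuple(
            SleepEpisode(row.start_hours, row.duration_hours, getattr(row, "kind", "main"))
            for row in df.itertuples()
        )
        return cls(float(meta["origin_clock"]), episodes, float(meta["horizon"]))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "origin_clock": self.origin_clock,
            "horizon": self.horizon,
            "episodes": [
                {"start_hours": e.start, "duration_hours": e.duration, "kind": e.kind}
                for e in self.episodes
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Schedule":
        doc = json.loads(Path(path).read_text())
        episodes = tuple(
            SleepEpisode(e["start_hours"], e["duration_hours"], e.get("kind", "main"))
            for e in doc["episodes"]
        )
        return cls(doc["origin_clock"], episodes, doc["horizon"])


# ---------------------------------------------------------------------------
# constructors


def build_entrained(
    n_days: int,
    bedtime_clock: float = 24.0,
    sleep_hours: float = 8.0,
    extra_days_horizon: int = 0,
) -> Schedule:
    """Habitual entrained schedule: one nightly episode per 24-h day.

    The time origin is the habitual wake-up time (bedtime + sleep length), so
    every simulated day runs wake-up to wake-up and day ``d`` occupies
    [24 d, 24 (d+1)).  Defaults (bedtime 24:00, 8 h of sleep) give the 1:2
    sleep-wake ratio of the entrained baseline.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0.0 < sleep_hours < 24.0:
        raise ValueError("sleep_hours must lie in (0, 24)")
    origin_clock = (bedtime_clock + sleep_hours) % 24.0
    wake_span = 24.0 - sleep_hours
    horizon = 24.0 * (n_days + extra_days_horizon)
    episodes = tuple(
        SleepEpisode(24.0 * d + wake_span, sleep_hours, "main") for d in range(n_days)
    )
    return Schedule(origin_clock, episodes, horizon)


def insert_nap(
    schedule: Schedule,
    nap_start_clock: float = 14.0,
    nap_hours: float = 2.0,
    day: int = 0,
) -> Schedule:
    """Add a daytime nap on day ``day`` (24-h days counted from the origin)."""
    if nap_hours <= 0:
        raise ValueError("nap duration must be positive")
    start = 24.0 * day + (nap_start_clock - schedule.origin_clock) % 24.0
    nap = SleepEpisode(start, nap_hours, "nap")
    for e in schedule.episodes:
        if start < e.end and nap.end > e.start:
            raise ValueError(
                f"nap [{start:.2f}, {nap.end:.2f}) overlaps episode [{e.start:.2f}, {e.end:.2f})"
            )
    return schedule.with_episode(nap)


def shift_main_sleep(schedule: Schedule, delta: float) -> Schedule:
    """Shift every main-sleep episode by ``delta`` hours (positive = delay)."""
    if abs(delta) >= 12.0:
        raise ValueError("|delta| must be < 12 h")
    if delta == 0.0:
        return schedule
    moved = []
    for e in schedule.episodes:
        if e.kind != "main":
            moved.append(e)
            continue
        start = e.start + delta
        if start < 0:
            raise ValueError("shift would move an episode before the origin")
        dur = e.duration
        if start >= schedule.horizon:
            continue  # fully beyond the horizon: drop (clip, never wrap)
        dur = min(dur, schedule.horizon - start)
        moved.append(SleepEpisode(start, dur, e.kind))
    moved.sort(key=lambda e: e.start)
    for a, b in zip(moved, moved[1:]):
        if b.start < a.end - 1e-9:
            raise ValueError("shift creates overlapping episodes")
    return Schedule(schedule.origin_clock, tuple(moved), schedule.horizon)


def build_fd(
    day_length: float = 28.0,
    sleep_to_wake: tuple[int, int] = (1, 5),
    n_fd_days: int = 7,
    adaptation_days: int = 2,
    bedtime_clock: float = 24.0,
    sleep_hours: float = 8.0,
) -> Schedule:
    """Forced-desynchrony schedule: entrained adaptation days, then 28-h days.

    Each FD day offers one sleep opportunity of ``day_length * s/(s+w)`` hours
    placed at the end of the day's wake span; consecutive FD days start
    ``day_length`` hours apart, the first at the adaptation wake-up time.
    """
    s, w = sleep_to_wake
    if s <= 0 or w <= 0 or int(s) != s or int(w) != w:
        raise ValueError("sleep_to_wake must be positive integers")
    if day_length <= 0:
        raise ValueError("day_length must be positive")
    base = build_entrained(adaptation_days, bedtime_clock, sleep_hours)
    fd_sleep = day_length * s / (s + w)
    fd_start = 24.0 * adaptation_days
    horizon = fd_start + day_length * n_fd_days
    episodes = list(base.episodes)
    for d in range(n_fd_days):
        day_end = fd_start + day_length * (d + 1)
        episodes.append(SleepEpisode(day_end - fd_sleep, fd_sleep, "fd"))
    return Schedule(base.origin_clock, tuple(episodes), horizon)


def build_ultrashort(
    sleep_min: float = 7.0,
    wake_min: float = 13.0,
    total: float = 24.0,
    origin_clock: float = 8.0,
    start_offset: float = 0.0,
) -> Schedule:
    """Ultra-short sleep-wake protocol: repeating brief nap opportunities.

    Defaults (7 min sleep / 13 min wake over 24 h) give 72 nap opportunities.
    """
    if sleep_min <= 0 or wake_min <= 0:
        raise ValueError("durations must be positive")
    cycle = (sleep_min + wake_min) / 60.0
    n = total / cycle
    if abs(n - round(n)) > 1e-6:
        raise ValueError("sleep+wake cycle must divide evenly into the total span")
    n = int(round(n))
    episodes = tuple(
        SleepEpisode(start_offset + i * cycle, sleep_min / 60.0, "ultrashort")
        for i in range(n)
    )
    return Schedule(origin_clock, episodes, start_offset + total)


def build_narcolepsy(n_days: int = 2, origin_clock: float = 0.0) -> Schedule:
    """Rule-generated polyphasic actogram of a hypothetical narcolepsy patient.

    Synthetic stand-in for an actometric recording: per 24-h day a fragmented
    night (00:00-06:00 with two 30-min awakenings) plus three 30-min daytime
    naps at 10:00, 14:00 and 17:30.
    """
    blocks = [
        (0.0, 1.5, "main"),
        (2.0, 1.5, "main"),
        (4.0, 2.0, "main"),
        (10.0, 0.5, "nap"),
        (14.0, 0.5, "nap"),
        (17.5, 0.5, "nap"),
    ]
    episodes = tuple(
        SleepEpisode(24.0 * d + start, dur, kind)
        for d in range(n_days)
        for start, dur, kind in blocks
    )
    return Schedule(origin_clock, episodes, 24.0 * n_days)
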