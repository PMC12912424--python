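"""Detection of the four circadian landmarks of the 24-h propensity curve.

Under entrained conditions the S.R propensity curve shows (a) a primary
nocturnal peak, (b) a secondary afternoon peak (the afternoon napping zone,
ANZ), (c) a morning minimum shortly after wake-up and (d) an early-evening
minimum (the wake-maintenance zone, WMZ).  The classifier works on a
moving-average-smoothed curve within one analysis window and reports times,
values, prominences and presence flags.

Presence criteria are explicit so "the ANZ disappears" is testable: the ANZ
requires a topographic prominence of at least ``anz_min_prominence_frac``
times the window's global maximum, and a WMZ must be a local minimum that is
distinct from the post-sleep morning minimum and at least
``boundary_margin_h`` away from any sleep-episode boundary (dips evoked by
an episode edge are homeostatic artefacts, not circadian landmarks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.signal import peak_prominences

from .params import FeatureConfig
from .schedules import Schedule

__all__ = [
    "FeatureSet",
    "smooth_moving_average",
    "detect_extrema",
    "classify_features",
    "classify_window",
    "anz_persistence_threshold",
    "PersistenceResult",
    "peak_ratio",
    "fd_feature_table",
]


def smooth_moving_average(values, window_h: float, dt: float):
    """Centred moving average with shrinking windows at the edges."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    if window_h < dt - 1e-12:
        raise ValueError("window must be at least one sample wide")
    half = int(round(window_h / (2.0 * dt)))
    if half == 0:
        return v.copy()
    c = np.concatenate(([0.0], np.cumsum(v)))
    n = v.size
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (c[hi] - c[lo]) / (hi - lo)


@dataclass(frozen=True)
class Extremum:
    time: float
    value: float
    kind: Literal["max", "min"]
    index: int  # sample index (plateau midpoint)


def detect_extrema(values, dt: float, t0: float = 0.0) -> list[Extremum]:
    """Interior extrema via strict sign changes of the first difference.

    Plateaus collapse to their midpoint; the returned kinds strictly
    alternate.  Monotone series yield an empty list.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("series must have at least 3 samples")
    d = np.diff(v)
    nz = np.nonzero(d)[0]
    out: list[Extremum] = []
    prev_sign = 0
    prev_idx = -1
    for j in nz:
        s = 1 if d[j] > 0 else -1
        if prev_sign != 0 and s != prev_sign:
            # plateau spans samples prev_idx+1 .. j (all equal values)
            mid = 0.5 * (prev_idx + 1 + j)
            idx = int(round(mid))
            kind = "max" if prev_sign > 0 else "min"
            out.append(Extremum(t0 + mid * dt, float(v[idx]), kind, idx))
        prev_sign = s
        prev_idx = j
    return out


@dataclass
class FeatureSet:
    """Classified circadian features of one analysis window."""

    window_start: float
    window_hours: float
    nocturnal_peak_time: float  # clock hours
    nocturnal_peak_value: float
    nocturnal_in_sleep: bool
    morning_min_time: float | None
    morning_min_value: float | None
    anz_time: float | None
    anz_value: float | None
    anz_prominence: float
    anz_present: bool
    wmz_time: float | None
    wmz_value: float | None
    wmz_present: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def n_present(self) -> int:
        return int(self.nocturnal_in_sleep) + int(self.morning_min_time is not None) + int(self.anz_present) + int(self.wmz_present)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        for key in ("nocturnal_peak_time", "morning_min_time", "anz_time", "wmz_time"):
            if doc[key] is not None:
                doc[key] = round(doc[key], 2)
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _in_clock_window(clock, window):
    lo, hi = window
    c = np.asarray(clock, dtype=float) % 24.0
    if lo <= hi:
        return (c >= lo) & (c <= hi)
    return (c >= lo) | (c <= hi)


def _boundary_distance(t: float, schedule: Schedule) -> float:
    edges = [x for e in schedule.episodes for x in (e.start, e.end)]
    return min(abs(t - x) for x in edges) if edges else np.inf


def classify_features(
    t,
    p,
    schedule: Schedule,
    window_start: float,
    window_hours: float = 24.0,
    config: FeatureConfig | None = None,
    smoothed: bool = False,
) -> FeatureSet:
    """Classify the circadian features of ``p`` over one analysis window.

    ``t``/``p`` are a uniform time grid and the matching propensity samples;
    the window is [window_start, window_start + window_hours).  ``p`` is
    smoothed with the configured moving average unless ``smoothed`` is set.
    """
    cfg = config or FeatureConfig()
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    mask = (t >= window_start - 1e-9) & (t < window_start + window_hours - 1e-9)
    ts = t[mask]
    if ts.size < 3:
        raise ValueError("window contains fewer than 3 samples")
    dt = float(ts[1] - ts[0])
    ps = p[mask] if smoothed else smooth_moving_average(p[mask], cfg.smooth_window_h, dt)
    clock = schedule.clock_at(ts)
    wake = ~schedule.is_sleep(ts)
    warnings: list[str] = []

    # (a) nocturnal peak: global maximum of the window
    imax = int(np.argmax(ps))
    has_sleep = schedule.total_sleep(window_start, window_start + window_hours) > 0
    if not has_sleep:
        warnings.append("window contains no scheduled sleep; global max reported anyway")
    noct_time = float(ts[imax])
    noct_val = float(ps[imax])

    extrema = detect_extrema(ps, dt, t0=float(ts[0])) if ts.size >= 3 else []
    maxima = [e for e in extrema if e.kind == "max"]
    minima = [e for e in extrema if e.kind == "min"]
    max_proms = (
        peak_prominences(ps, [e.index for e in maxima])[0] if maxima else np.array([])
    )

    # (b) ANZ: largest afternoon local max during scheduled wakefulness
    anz_time = anz_val = None
    anz_prom = 0.0
    anz_present = False
    cand = [
        (e, float(pr))
        for e, pr in zip(maxima, max_proms)
        if _in_clock_window(schedule.clock_at(e.time), cfg.anz_clock_window)
        and not schedule.is_sleep(np.array([e.time]))[0]
    ]
    if cand:
        e, pr = max(cand, key=lambda c: c[0].value)
        anz_time, anz_val, anz_prom = float(e.time), float(e.value), pr
        anz_present = pr >= cfg.anz_min_prominence_frac * noct_val

    # (c) morning minimum: lowest local min within a few hours of wake-up
    ends = [e.end for e in schedule.episodes if window_start - 1e-9 <= e.end <= window_start + window_hours]
    wake_up = min(ends) if ends else float(ts[0])
    # smoothing can displace the post-sleep dip slightly before wake-up
    span = (wake_up - cfg.smooth_window_h / 2.0, wake_up + cfg.morning_span_h)
    m_cand = [e for e in minima if span[0] - 1e-9 <= e.time <= span[1] + 1e-9]
    if m_cand:
        m = min(m_cand, key=lambda e: e.value)
        morning_time, morning_val = float(m.time), float(m.value)
    else:
        sub = (ts >= span[0] - 1e-9) & (ts <= span[1] + 1e-9)
        if np.any(sub):
            i = int(np.argmin(np.where(sub, ps, np.inf)))
            morning_time, morning_val = float(ts[i]), float(ps[i])
            warnings.append("morning minimum taken at window/segment boundary")
        else:
            morning_time = morning_val = None

    # (d) WMZ: early-evening circadian minimum during wakefulness,
    # distinct from the post-sleep minimum and clear of episode edges
    wmz_time = wmz_val = None
    wmz_present = False
    w_cand = [
        e
        for e in minima
        if _in_clock_window(schedule.clock_at(e.time), cfg.wmz_clock_window)
        and (not cfg.wmz_require_wake or not schedule.is_sleep(np.array([e.time]))[0])
        and _boundary_distance(e.time, schedule) >= cfg.boundary_margin_h
    ]
    if w_cand:
        min_proms = peak_prominences(-ps, [e.index for e in w_cand])[0]
        order = np.argsort([e.value for e in w_cand])
        e = w_cand[int(order[0])]
        pr = float(min_proms[int(order[0])])
        wmz_time, wmz_val = float(e.time), float(e.value)
        distinct = morning_time is None or abs(e.time - morning_time) > 1e-6
        wmz_present = distinct and pr >= cfg.wmz_min_prominence_frac * noct_val

    return FeatureSet(
        window_start=window_start,
        window_hours=window_hours,
        nocturnal_peak_time=float(schedule.clock_at(noct_time)),
        nocturnal_peak_value=noct_val,
        nocturnal_in_sleep=has_sleep,
        morning_min_time=None if morning_time is None else float(schedule.clock_at(morning_time)),
        morning_min_value=morning_val,
        anz_time=None if anz_time is None else float(schedule.clock_at(anz_time)),
        anz_value=anz_val,
        anz_prominence=anz_prom,
        anz_present=anz_present,
        wmz_time=None if wmz_time is None else float(schedule.clock_at(wmz_time)),
        wmz_value=wmz_val,
        wmz_present=wmz_present,
        warnings=warnings,
    )


def classify_window(trajectory, schedule, window_start, window_hours=24.0, config=None):
    """Convenience wrapper taking an engine :class:`~srsleep.engine.Trajectory`."""
    return classify_features(
        trajectory.t, trajectory.P, schedule, window_start, window_hours, config
    )


@dataclass(frozen=True)
class PersistenceResult:
    threshold_h: float
    violation: bool
    pattern: tuple[bool, ...]
    warning: str | None = None


def anz_persistence_threshold(sweep: Sequence[tuple[float, FeatureSet]]) -> PersistenceResult:
    """Largest shift at which the ANZ is still detected in a shift sweep.

    Assumes presence is monotone in the shift magnitude; a non-monotone
    pattern is flagged.  An ANZ missing already at shift 0 signals a
    calibration failure and returns -1.
    """
    items = sorted(sweep, key=lambda x: x[0])
    pattern = tuple(fs.anz_present for _, fs in items)
    if not pattern or not pattern[0]:
        return PersistenceResult(-1.0, False, pattern, "ANZ absent at zero shift")
    last = max(d for (d, fs) in items if fs.anz_present)
    seen_absent = False
    violation = False
    for present in pattern:
        if not present:
            seen_absent = True
        elif seen_absent:
            violation = True
    return PersistenceResult(float(last), violation, pattern)


def peak_ratio(fs: FeatureSet) -> float | None:
    """Secondary-to-primary peak ratio; None when the ANZ is absent."""
    if not fs.anz_present or fs.anz_value is None:
        return None
    return float(fs.anz_value / fs.nocturnal_peak_value)


def fd_feature_table(
    trajectory,
    schedule: Schedule,
    fd_start: float,
    day_hours: float,
    n_days: int,
    config: FeatureConfig | None = None,
) -> list[FeatureSet]:
    """Per-FD-day feature classification (day d spans one rest-activity cycle).

    The WMZ wake requirement is dropped here: when the sleep opportunity
    covers the early-evening clock window, the circadian dip expresses
    within sleep (as an efficiency trough) rather than during wakefulness.
    """
    cfg = replace(config or FeatureConfig(), wmz_require_wake=False)
    return [
        classify_window(
            trajectory, schedule, fd_start + day_hours * d, day_hours, cfg
        )
        for d in range(n_days)
    ]
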