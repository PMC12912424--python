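"""Closed-form process dynamics of the S.R model.

The homeostat S follows saturating exponentials (rise in wake, fall in
sleep); the circadian REM-sleep drive R is a raised cosine of clock time
whose modulation can be attenuated about its mesor; total sleep propensity is
the product P = S * R.  The classic threshold pair H/L of the S-C model is
provided for side-by-side simulation, and REM latencies convert to drive
units through a declared reciprocal transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .params import LatencyMap, RParams, SCParams, SParams, _shape_mean

__all__ = [
    "s_step",
    "s_rise",
    "s_fall",
    "r_value",
    "propensity",
    "thresholds_hl",
    "rem_latency_to_r",
    "RemTransformResult",
    "entrained_fixed_points",
]

State = Literal["wake", "sleep"]


def s_rise(s0, dt, params: SParams):
    """S after ``dt`` hours of wakefulness, UA - (UA - s0) * exp(-dt/tau_rise)."""
    ua = params.upper_asymptote
    return ua - (ua - np.asarray(s0, dtype=float)) * np.exp(-np.asarray(dt, dtype=float) / params.tau_rise)


def s_fall(s0, dt, params: SParams):
    """S after ``dt`` hours of sleep, LA + (s0 - LA) * exp(-dt/tau_fall)."""
    la = params.lower_asymptote
    return la + (np.asarray(s0, dtype=float) - la) * np.exp(-np.asarray(dt, dtype=float) / params.tau_fall)


def s_step(s0: float, dt: float, state: State, params: SParams) -> float:
    """Advance the homeostat by ``dt`` hours in the given behavioural state."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if not (params.lower_asymptote - 1e-12 <= s0 <= params.upper_asymptote + 1e-12):
        raise ValueError("s0 outside [lower_asymptote, upper_asymptote]")
    if state == "wake":
        return float(s_rise(s0, dt, params))
    if state == "sleep":
        return float(s_fall(s0, dt, params))
    raise ValueError(f"unknown state {state!r}")


def r_value(clock_t, params: RParams, amplitude_scale=1.0):
    """Circadian REM-sleep drive at clock time(s) ``clock_t``.

    The full-amplitude curve is ``floor + amplitude * ((1 + cos(psi))/2) **
    k`` with ``psi = theta + skew * (1 - cos(theta))`` and ``theta = 2 pi (t
    - acrophase)/24``; negative skew slows the post-peak decline and
    sharpens/delays the trough while keeping the maximum at the acrophase.
    ``amplitude_scale`` in [0, 1] shrinks the modulation about the curve's
    circadian mean (mesor), so a fully attenuated drive is flat at the mesor
    — high REM pressure at all phases with no circadian relief, as seen
    under severe sleep restriction.
    """
    scale = np.asarray(amplitude_scale, dtype=float)
    if np.any(scale < -1e-12) or np.any(scale > 1.0 + 1e-12):
        raise ValueError("amplitude_scale must lie in [0, 1]")
    phase_h = np.mod(np.asarray(clock_t, dtype=float) - params.acrophase, params.period)
    theta = 2.0 * math.pi * phase_h / params.period
    psi = theta + params.skew * (1.0 - np.cos(theta))
    shape = ((1.0 + np.cos(psi)) / 2.0) ** params.shape_exponent
    m = _shape_mean(params.shape_exponent, params.skew)
    out = params.floor + params.amplitude * (m + scale * (shape - m))
    return out if out.ndim else float(out)


def propensity(s, r):
    """Total sleep propensity P = S * R (both inputs strictly positive)."""
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(s <= 0) or np.any(r <= 0):
        raise ValueError("propensity requires strictly positive S and R")
    out = s * r
    return out if out.ndim else float(out)


def thresholds_hl(clock_t, params: SCParams):
    """Upper (sleep-onset) and lower (awakening) thresholds of the S-C model."""
    h = params.h_at(clock_t)
    l = params.l_at(clock_t)
    return (h if h.ndim else float(h), l if l.ndim else float(l))


@dataclass(frozen=True)
class RemTransformResult:
    clock_t: np.ndarray
    r: np.ndarray
    flat_input: bool = False


def rem_latency_to_r(
    latencies: Sequence[tuple[float, float]],
    offset_min: float = 10.0,
    floor: float = 0.05,
    mode: Literal["minmax", "calibrated"] = "minmax",
    latency_map: LatencyMap | None = None,
) -> RemTransformResult:
    """Convert (clock hour, REM latency in minutes) pairs to drive units.

    Raw REM pressure is ``1 / (latency + offset_min)``; short latencies mean
    high pressure.  ``minmax`` rescales the raw values linearly onto
    [floor, 1] (the sample extremes define the span); ``calibrated`` inverts
    the package's declared :class:`LatencyMap` instead, preserving absolute
    amplitude.  Identical latencies make min-max undefined; the result is then
    flat at (floor + 1)/2 with ``flat_input`` set.
    """
    arr = np.asarray(latencies, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("latencies must be (clock_t, minutes) pairs")
    clock_t, lat = arr[:, 0], arr[:, 1]
    if np.any(lat <= 0):
        raise ValueError("latencies must be positive")
    if len(np.unique(clock_t)) < 2:
        raise ValueError("need at least 2 distinct clock times")
    if mode == "calibrated":
        lmap = latency_map or LatencyMap.from_anchors(floor=floor, offset_min=offset_min)
        return RemTransformResult(clock_t, np.asarray(lmap.r_of_latency(lat)))
    raw = 1.0 / (lat + offset_min)
    lo, hi = float(np.min(raw)), float(np.max(raw))
    if hi - lo < 1e-15:
        mid = (floor + 1.0) / 2.0
        return RemTransformResult(clock_t, np.full_like(raw, mid), flat_input=True)
    r = floor + (1.0 - floor) * (raw - lo) / (hi - lo)
    return RemTransformResult(clock_t, r)


def entrained_fixed_points(
    params: SParams, wake_hours: float = 16.0, sleep_hours: float = 8.0
) -> tuple[float, float]:
    """(S at wake-up, S at sleep onset) of the periodic entrained cycle.

    Closed form of the fixed point of one wake+sleep iteration; the engine
    uses the wake-up value to start simulations on the limit cycle.
    """
    ua, la = params.upper_asymptote, params.lower_asymptote
    a = math.exp(-wake_hours / params.tau_rise)
    b = math.exp(-sleep_hours / params.tau_fall)
    # s_high = ua - (ua - s_low) a ; s_low = la + (s_high - la) b
    s_high = (ua * (1 - a) + a * (la * (1 - b))) / (1 - a * b)
    s_low = la + (s_high - la) * b
    return s_low, s_high
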