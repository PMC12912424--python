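"""Synthetic observation generators.

No public dataset exists for the protocols the model addresses, so every fit
and round trip is exercised on generated data with the right statistical
structure: (a) nap-protocol REM-latency series carrying a 24-h circadian
modulation plus multiplicative lognormal noise, and (b) per-nap EEG
synchronization ramps (0-10 arbitrary units, one sample per 30 s) of an
ultra-short sleep-wake protocol, from which a 24-h propensity curve is
re-derived the way the original nap analyses did — per-nap summary plus a
2-h moving average.

All generators are pure functions of their parameters and the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import smooth_moving_average
from .fitting import RemLatencyObs
from .params import LatencyMap, RParams, default_params
from .processes import r_value
from .schedules import Schedule

__all__ = [
    "NapRamp",
    "gen_rem_latency",
    "gen_nap_sync_ramps",
    "ramps_to_propensity",
    "write_ramps_csv",
    "read_ramps_csv",
]

RAMP_SAMPLE_S = 30.0
SYNC_MAX = 10.0


@dataclass(frozen=True)
class NapRamp:
    """EEG-synchronization ramp of one brief nap (arbitrary 0-10 scale).

    10 means fully desynchronized (awake), 0 fully synchronized; samples run
    every 30 s from nap onset.
    """

    nap_index: int
    start_clock: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if np.any(s < 0.0) or np.any(s > SYNC_MAX):
            raise ValueError("samples must lie in [0, 10]")


def gen_rem_latency(
    params: RParams | None = None,
    n_per_timepoint: int = 1,
    timepoints: Sequence[float] | None = None,
    noise_sd_min: float = 0.0,
    seed: int | None = None,
    latency_map: LatencyMap | None = None,
    amplitude_scale: float = 1.0,
    day_index: int | None = None,
) -> list[RemLatencyObs]:
    """REM-latency observations with circadian modulation plus noise.

    Clean latencies invert the declared latency map at ``r_value(t)``; noise
    is multiplicative lognormal, moment-matched so the standard deviation on
    the minute scale equals ``noise_sd_min`` at each timepoint.  Latency is
    shortest at the acrophase (REM pressure highest).
    """
    if noise_sd_min < 0:
        raise ValueError("noise_sd_min must be >= 0")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    defaults = default_params()
    params = params or defaults["r_process"]
    lmap = latency_map or defaults["latency_map"]
    if timepoints is None:
        timepoints = np.arange(0.0, 24.0, 1.0)
    timepoints = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    out: list[RemLatencyObs] = []
    for t in timepoints:
        r = r_value(float(t) % 24.0, params, amplitude_scale)
        clean = float(lmap.latency_of_r(r))
        for _ in range(n_per_timepoint):
            lat = clean
            if noise_sd_min > 0:
                cv = noise_sd_min / clean
                sigma2 = math.log1p(cv * cv)
                lat = clean * rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2))
            out.append(RemLatencyObs(float(t) % 24.0, float(lat), day_index))
    return out


def gen_nap_sync_ramps(
    trajectory,
    ultrashort_schedule: Schedule,
    noise_sd: float = 0.0,
    seed: int | None = None,
    decay_rate_per_min_per_p: float = 1.0,
) -> list[NapRamp]:
    """EEG-synchronization ramps for every nap of an ultra-short schedule.

    Each nap starts fully desynchronized (10) and decays exponentially toward
    ``10 * (1 - P)`` with rate proportional to the propensity P at nap start,
    so sleepier naps synchronize faster and deeper.  Gaussian noise of sd
    ``noise_sd`` is added per sample and the result clipped to [0, 10].
    """
    if seed is None and noise_sd > 0:
        raise ValueError("a seed is required when noise is requested")
    rng = np.random.default_rng(seed)
    t_lo, t_hi = float(trajectory.t[0]), float(trajectory.t[-1])
    ramps: list[NapRamp] = []
    for i, e in enumerate(ultrashort_schedule.episodes):
        if e.start < t_lo - 1e-9 or e.end > t_hi + 1e-9:
            raise ValueError(f"nap [{e.start:.3f}, {e.end:.3f}) outside the trajectory span")
        p = float(trajectory.p_at(e.start))
        n = int(round(e.duration * 3600.0 / RAMP_SAMPLE_S))
        tau_min = np.arange(n) * (RAMP_SAMPLE_S / 60.0)
        floor = SYNC_MAX * (1.0 - p)
        clean = floor + (SYNC_MAX - floor) * np.exp(-decay_rate_per_min_per_p * p * tau_min)
        noisy = clean + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
        ramps.append(
            NapRamp(i, float(ultrashort_schedule.clock_at(e.start)), np.clip(noisy, 0.0, SYNC_MAX))
        )
    return ramps


@dataclass(frozen=True)
class RecoveredPropensity:
    t: np.ndarray          # nap start times, hours since schedule origin
    clock_t: np.ndarray
    value: np.ndarray      # smoothed per-nap sleepiness summary (a.u.)
    raw: np.ndarray        # unsmoothed summaries


def ramps_to_propensity(
    ramps: Sequence[NapRamp],
    ultrashort_schedule: Schedule,
    window: float = 2.0,
) -> RecoveredPropensity:
    """24-h propensity estimate from a ramp ensemble.

    The per-nap summary is 10 minus the final synchronization sample (higher
    = sleepier), placed at nap start, then smoothed with a centred moving
    average — the nap-study reduction of the ramp ensemble to a daily curve.
    """
    if len(ramps) < 3:
        raise ValueError("need at least 3 ramps")
    eps = ultrashort_schedule.episodes
    if len(eps) != len(ramps):
        raise ValueError("schedule and ramp ensemble sizes differ")
    t = np.array([e.start for e in eps])
    raw = np.array([SYNC_MAX - float(np.asarray(r.samples)[-1]) for r in ramps])
    dt = float(t[1] - t[0]) if t.size > 1 else window
    smooth = smooth_moving_average(raw, window, dt)
    return RecoveredPropensity(t, np.asarray(ultrashort_schedule.clock_at(t)), smooth, raw)


def write_ramps_csv(ramps: Sequence[NapRamp], path: str | Path) -> None:
    rows = [
        (r.nap_index, r.start_clock, j, v)
        for r in ramps
        for j, v in enumerate(np.asarray(r.samples))
    ]
    pd.DataFrame(
        rows, columns=["nap_index", "start_clock", "sample_index", "sync_value"]
    ).to_csv(path, index=False, float_format="%.6f")


def read_ramps_csv(path: str | Path) -> list[NapRamp]:
    df = pd.read_csv(path)
    out = []
    for idx, grp in df.groupby("nap_index"):
        grp = grp.sort_values("sample_index")
        out.append(NapRamp(int(idx), float(grp.start_clock.iloc[0]), grp.sync_value.to_numpy()))
    return out
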