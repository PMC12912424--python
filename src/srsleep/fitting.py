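"""Estimation of the circadian REM drive R from REM-latency observations.

The model is linear in amplitude once the acrophase is fixed, so the fit
grid-searches the acrophase in 0.1-h steps and solves the amplitude in
closed form — cheap, deterministic and free of local minima.  Latencies are
taken to drive units through the package's declared reciprocal transform
(:class:`~srsleep.params.LatencyMap`), which preserves absolute amplitude;
the data-driven min-max rescaling of
:func:`~srsleep.processes.rem_latency_to_r` is kept for drive-curve
construction but is a biased basis for amplitude estimation because sample
extremes are inflated by noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import AttenuationProfile, LatencyMap, RParams, default_params

__all__ = [
    "RemLatencyObs",
    "FitResult",
    "fit_r_cosinor",
    "fit_attenuation_endpoints",
    "fit_narcolepsy_r",
    "read_obs_csv",
    "write_obs_csv",
]


@dataclass(frozen=True)
class RemLatencyObs:
    """One REM-latency observation: clock hour, latency in minutes."""

    clock_t: float
    latency: float
    day_index: int | None = None

    def __post_init__(self) -> None:
        if self.latency <= 0:
            raise ValueError("latency must be positive")
        if not 0.0 <= self.clock_t < 24.0:
            raise ValueError("clock_t must lie in [0, 24)")


@dataclass
class FitResult:
    params: RParams
    residual_rms: float
    n_obs: int
    warnings: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "floor": self.params.floor,
            "amplitude": self.params.amplitude,
            "acrophase": self.params.acrophase,
            "shape_exponent": self.params.shape_exponent,
            "residual_rms": self.residual_rms,
            "n_obs": self.n_obs,
            "warnings": self.warnings,
            "settings": self.settings,
        }


def _check_span(clock: np.ndarray) -> None:
    if clock.size < 6:
        raise ValueError("need at least 6 observations")
    if float(np.max(clock) - np.min(clock)) < 12.0:
        raise ValueError("observations must span at least 12 h of clock time")


def _shape(clock: np.ndarray, phi: float, k: float, skew: float = 0.0) -> np.ndarray:
    theta = 2.0 * math.pi * (clock - phi) / 24.0
    psi = theta + skew * (1.0 - np.cos(theta))
    return ((1.0 + np.cos(psi)) / 2.0) ** k


def _fit_free_intercept(
    clock: np.ndarray, y: np.ndarray, k: float, skew: float, phi_step: float
) -> tuple[float, float, float]:
    """Grid-search phi, solve (intercept, slope) by LSQ; returns (phi, intercept, slope).

    The slope is the modulation amplitude riding on the shape function —
    invariant to any level shift, which is what mesor-pivot attenuation
    changes.
    """
    best = None
    for phi in np.arange(0.0, 24.0, phi_step):
        x = _shape(clock, phi, k, skew)
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        slope = max(float(coef[1]), 0.0)
        pred = coef[0] + slope * x
        sse = float(np.sum((y - pred) ** 2))
        if best is None or sse < best[0]:
            best = (sse, float(phi), float(coef[0]), slope)
    _, phi, intercept, slope = best
    return phi, intercept, slope


def fit_r_cosinor(
    obs: Sequence[RemLatencyObs],
    floor: float = 0.05,
    k: float = 1.0,
    skew: float = 0.0,
    latency_map: LatencyMap | None = None,
    phi_step: float = 0.1,
) -> FitResult:
    """Least-squares raised-cosine fit of amplitude and acrophase.

    ``floor`` and the shape parameters (``k``, ``skew``) are held fixed; the
    acrophase is grid-searched over [0, 24) in ``phi_step`` increments and
    the amplitude solved in closed form at each candidate.
    """
    lmap = latency_map or default_params()["latency_map"]
    clock = np.array([o.clock_t for o in obs], dtype=float)
    lat = np.array([o.latency for o in obs], dtype=float)
    _check_span(clock)
    y = np.asarray(lmap.r_of_latency(lat)) - floor

    warnings: list[str] = []
    if float(np.ptp(y)) < 1e-12:
        params = RParams(floor=floor, amplitude=0.0, acrophase=0.0, shape_exponent=k, skew=skew)
        warnings.append("flat transformed data; amplitude set to 0")
        return FitResult(params, 0.0, len(obs), warnings, {"floor": floor, "k": k})

    best = None
    for phi in np.arange(0.0, 24.0, phi_step):
        x = _shape(clock, phi, k, skew)
        denom = float(x @ x)
        if denom == 0.0:
            continue
        a = max(0.0, float(x @ y) / denom)
        sse = float(np.sum((y - a * x) ** 2))
        if best is None or sse < best[0]:
            best = (sse, phi, a)
    sse, phi, a = best
    a = min(a, 1.0 - floor)  # drive ceiling
    if a == 0.0:
        warnings.append("no circadian modulation recovered (amplitude 0)")
    params = RParams(floor=floor, amplitude=a, acrophase=float(phi % 24.0), shape_exponent=k, skew=skew)
    rms = math.sqrt(sse / len(obs))
    return FitResult(
        params, rms, len(obs), warnings,
        {"floor": floor, "k": k, "skew": skew, "phi_step": phi_step},
    )


def fit_attenuation_endpoints(
    obs: Sequence[RemLatencyObs],
    n_days: int | None = None,
    floor: float = 0.05,
    k: float = 1.0,
    skew: float = 0.0,
    latency_map: LatencyMap | None = None,
    day_hours: float = 28.0,
    origin_h: float = 0.0,
) -> AttenuationProfile:
    """Amplitude-attenuation profile from first- and last-day observations.

    The first FD day anchors scale 1.0; the final day's scale is the ratio of
    its fitted amplitude to the first day's, clipped to [0, 1], with linear
    interpolation in between (the intermediate stages are not observed).
    """
    days = sorted({o.day_index for o in obs if o.day_index is not None})
    if len(days) < 2:
        raise ValueError("need observations on at least a first and a last day")
    d0, d1 = days[0], days[-1]
    lmap = latency_map or default_params()["latency_map"]

    def day_amplitude(day):
        sub = [o for o in obs if o.day_index == day]
        clock = np.array([o.clock_t for o in sub], dtype=float)
        _check_span(clock)
        y = np.asarray(lmap.r_of_latency(np.array([o.latency for o in sub])))
        # free intercept: attenuation pivots about the mesor, so only the
        # modulation amplitude (slope on the shape function) carries scale
        _, _, slope = _fit_free_intercept(clock, y, k, skew, 0.1)
        return slope

    a0, a1 = day_amplitude(d0), day_amplitude(d1)
    if a0 <= 0.0:
        raise ValueError("baseline-day amplitude is zero; attenuation profile undefined")
    end = float(np.clip(a1 / a0, 0.0, 1.0))
    span = float(n_days if n_days is not None else (d1 - d0))
    return AttenuationProfile(
        day_scales=((0.0, 1.0), (span, end)), origin_h=origin_h, day_hours=day_hours
    )


def fit_narcolepsy_r(
    msltl: Sequence[RemLatencyObs],
    k: float = 1.0,
    skew: float = 0.0,
    offset_min: float = 10.0,
    phi_step: float = 0.1,
    sorem_cutoff_min: float = 15.0,
) -> FitResult:
    """Ceiling-constrained R fit for sleep-onset-REM (narcolepsy) latencies.

    Latencies in the SOREM regime (values below ``sorem_cutoff_min``) are
    mapped with the saturating absolute transform r = offset/(latency +
    offset), and floor and amplitude are both fitted under the ceiling
    constraint floor + amplitude <= 1: uniformly short latencies force a high
    floor and a small residual amplitude.  Observations without any SOREM
    latency are outside this regime and fall back to the healthy cosinor fit.
    """
    lat = np.array([o.latency for o in msltl], dtype=float)
    clock = np.array([o.clock_t for o in msltl], dtype=float)
    if not np.any(lat < sorem_cutoff_min):
        return fit_r_cosinor(msltl, k=k, skew=skew, phi_step=phi_step)
    _check_span(clock)
    lmap = LatencyMap.narcolepsy(offset_min)
    r = np.asarray(lmap.r_of_latency(lat))

    best = None
    for phi in np.arange(0.0, 24.0, phi_step):
        x = _shape(clock, phi, k, skew)
        # unconstrained LSQ of r ~ floor + a * x
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, r, rcond=None)
        f0, a = float(coef[0]), float(coef[1])
        a = max(a, 0.0)
        if f0 + a > 1.0:  # ceiling active: re-solve on the boundary f0 = 1 - a
            z = 1.0 - x
            denom = float(z @ z)
            a = float(z @ (1.0 - r)) / denom if denom > 0 else 0.0
            a = float(np.clip(a, 0.0, 0.999))
            f0 = 1.0 - a
        f0 = max(f0, 1e-6)
        pred = f0 + a * x
        sse = float(np.sum((r - pred) ** 2))
        if best is None or sse < best[0]:
            best = (sse, phi, f0, a)
    sse, phi, f0, a = best
    params = RParams(floor=f0, amplitude=a, acrophase=float(phi % 24.0), shape_exponent=k, skew=skew)
    return FitResult(
        params,
        math.sqrt(sse / len(msltl)),
        len(msltl),
        [],
        {"transform": "saturating", "offset_min": offset_min, "k": k, "skew": skew},
    )


# ---------------------------------------------------------------------------
# observation CSV round trip


def write_obs_csv(obs: Sequence[RemLatencyObs], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "clock_hours": [o.clock_t for o in obs],
            "latency_min": [o.latency for o in obs],
            "day_index": [o.day_index if o.day_index is not None else -1 for o in obs],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_obs_csv(path: str | Path) -> list[RemLatencyObs]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples():
        day = int(row.day_index) if "day_index" in df.columns else -1
        out.append(
            RemLatencyObs(float(row.clock_hours), float(row.latency_min), None if day < 0 else day)
        )
    return out
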