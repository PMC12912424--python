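"""Parameter records for the homeostatic process S, the circadian REM-sleep
drive R, the classic threshold process (S-C model), and the auxiliary
calibration objects (FD amplitude-attenuation profile, REM-latency map).

All times are decimal hours; clock times live on [0, 24). Drive levels are
dimensionless arbitrary units (a.u.). Shipped defaults are a single
calibration, stored in ``data/default_params.yaml`` and loaded through
:func:`default_params`; nothing numerical is hard-coded in the operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SParams",
    "RParams",
    "SCParams",
    "AttenuationProfile",
    "LatencyMap",
    "load_params",
    "save_params",
    "default_params",
    "FeatureConfig",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SParams:
    """Saturating-exponential homeostatic sleep pressure.

    S rises toward ``upper_asymptote`` during wakefulness with time constant
    ``tau_rise`` and decays toward ``lower_asymptote`` during sleep with time
    constant ``tau_fall``.  ``s_init`` is the level at the start of a
    simulation; ``None`` asks the engine to use the entrained fixed point.
    """

    upper_asymptote: float = 1.0
    lower_asymptote: float = 0.05
    tau_rise: float = 18.2
    tau_fall: float = 4.2
    s_init: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_asymptote < self.upper_asymptote):
            raise ValueError("require 0 < lower_asymptote < upper_asymptote")
        if self.tau_rise <= 0 or self.tau_fall <= 0:
            raise ValueError("time constants must be positive")
        if self.s_init is not None and not (
            self.lower_asymptote <= self.s_init <= self.upper_asymptote
        ):
            raise ValueError("s_init must lie within [lower_asymptote, upper_asymptote]")


@lru_cache(maxsize=64)
def _shape_mean(k: float, skew: float = 0.0) -> float:
    """Cycle mean of the (possibly skewed) raised-cosine shape function.

    For skew = 0 this is Gamma(k+1/2)/(sqrt(pi) Gamma(k+1)); with skew the
    mean is taken numerically on a fine grid (the phase modulation used for
    the skew preserves the cycle but not the closed form).
    """
    if skew == 0.0:
        from scipy.special import gammaln

        return float(math.exp(gammaln(k + 0.5) - gammaln(k + 1.0)) / math.sqrt(math.pi))
    theta = np.linspace(-math.pi, math.pi, 4096, endpoint=False)
    psi = theta + skew * (1.0 - np.cos(theta))
    return float(np.mean(((1.0 + np.cos(psi)) / 2.0) ** k))


@dataclass(frozen=True)
class RParams:
    """Raised-cosine circadian REM-sleep drive.

    ``floor`` is the minimum of the full-amplitude curve, ``amplitude`` its
    peak-to-trough range, ``acrophase`` the clock hour of the maximum and
    ``shape_exponent`` an optional sharpening power (>= 1).  ``skew``
    modulates the phase of the cosine (negative values give a slow post-peak
    decline with a sharp, delayed trough — the asymmetry the empirical
    REM-latency curve shows, with the evening propensity minimum only a few
    hours before habitual bedtime).  Amplitude attenuation (forced
    desynchrony) scales the modulation about the curve's circadian mean, so
    an attenuated drive flattens toward its mesor rather than collapsing
    onto the floor.
    """

    floor: float = 0.05
    amplitude: float = 0.95
    acrophase: float = 6.9
    period: float = 24.0
    shape_exponent: float = 1.0
    skew: float = 0.0

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError("floor must be strictly positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.floor + self.amplitude > 1.0 + 1e-12:
            raise ValueError("floor + amplitude must not exceed 1")
        if not 0.0 <= self.acrophase < 24.0:
            raise ValueError("acrophase must lie in [0, 24)")
        if self.period != 24.0:
            raise ValueError("period is fixed at 24 h")
        if self.shape_exponent < 1.0:
            raise ValueError("shape_exponent must be >= 1")
        if not -0.9 <= self.skew <= 0.9:
            raise ValueError("skew must lie in (-0.9, 0.9)")

    @property
    def mesor(self) -> float:
        """Circadian mean of the full-amplitude drive."""
        return self.floor + self.amplitude * _shape_mean(self.shape_exponent, self.skew)


@dataclass(frozen=True)
class SCParams:
    """Sinusoidal upper (H) and lower (L) thresholds of the classic model.

    Sleep onset is triggered when S reaches H, awakening when S reaches L.
    ``skew_l`` adds a fixed 25%-weight second harmonic to L.
    """

    h_mean: float = 0.60
    h_amp: float = 0.10
    l_mean: float = 0.17
    l_amp: float = 0.10
    phase: float = 22.0
    skew_l: bool = False

    def h_at(self, clock_t):
        theta = TWO_PI * (np.asarray(clock_t, dtype=float) - self.phase) / 24.0
        return self.h_mean + self.h_amp * np.sin(theta)

    def l_at(self, clock_t):
        theta = TWO_PI * (np.asarray(clock_t, dtype=float) - self.phase) / 24.0
        base = np.sin(theta)
        if self.skew_l:
            base = 0.75 * base + 0.25 * np.sin(2.0 * theta)
        return self.l_mean + self.l_amp * base

    def __post_init__(self) -> None:
        if self.h_amp < 0 or self.l_amp < 0:
            raise ValueError("threshold amplitudes must be non-negative")
        grid = np.arange(0.0, 24.0, 0.05)
        if np.min(self.h_at(grid) - self.l_at(grid)) <= 0:
            raise ValueError("thresholds cross: H(t) must exceed L(t) at all clock times")


@dataclass(frozen=True)
class AttenuationProfile:
    """Piecewise-linear circadian-amplitude scale across protocol days.

    ``day_scales`` maps day index -> amplitude scale in [0, 1]; day 0 must be
    1.0 (unattenuated baseline).  Interpolation is linear in continuous day
    number; the scale is held constant beyond the listed endpoints.
    ``origin_h``/``day_hours`` convert simulation time to day number.
    """

    day_scales: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    origin_h: float = 0.0
    day_hours: float = 28.0

    def __post_init__(self) -> None:
        days = [d for d, _ in self.day_scales]
        scales = [s for _, s in self.day_scales]
        if sorted(days) != days:
            raise ValueError("day_scales must be sorted by day index")
        if any(not 0.0 <= s <= 1.0 for s in scales):
            raise ValueError("amplitude scales must lie in [0, 1]")
        if abs(dict(self.day_scales).get(0.0, scales[0]) - 1.0) > 1e-12 or days[0] > 0:
            raise ValueError("scale at day 0 must equal 1")
        if self.day_hours <= 0:
            raise ValueError("day_hours must be positive")

    def scale_at_day(self, day):
        days = np.array([d for d, _ in self.day_scales])
        scales = np.array([s for _, s in self.day_scales])
        return np.interp(np.asarray(day, dtype=float), days, scales)

    def scale_at_time(self, t_hours):
        return self.scale_at_day((np.asarray(t_hours, dtype=float) - self.origin_h) / self.day_hours)


@dataclass(frozen=True)
class LatencyMap:
    """Declared mapping between REM latency (minutes) and drive level r.

    The reciprocal pressure scale is ``raw = 1 / (latency + offset_min)``; the
    map states the affine calibration ``raw = alpha * r + beta`` tying raw
    pressure to drive units, so ``latency(r) = 1/(alpha r + beta) - offset``.
    ``narcolepsy()`` returns the saturating anchor-free variant
    ``r = offset / (latency + offset)`` (alpha = 1/offset, beta = 0), which
    sends sleep-onset REM latencies near zero to r near 1.
    """

    alpha: float
    beta: float
    offset_min: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.offset_min < 0:
            raise ValueError("offset must be non-negative")

    def latency_of_r(self, r):
        r = np.asarray(r, dtype=float)
        raw = self.alpha * r + self.beta
        if np.any(raw <= 0):
            raise ValueError("drive level outside the invertible range of the map")
        return 1.0 / raw - self.offset_min

    def r_of_latency(self, latency_min):
        lat = np.asarray(latency_min, dtype=float)
        if np.any(lat <= 0):
            raise ValueError("latencies must be positive")
        raw = 1.0 / (lat + self.offset_min)
        return (raw - self.beta) / self.alpha

    @classmethod
    def from_anchors(
        cls,
        lat_at_ceiling: float = 60.0,
        lat_at_floor: float = 200.0,
        floor: float = 0.05,
        offset_min: float = 10.0,
    ) -> "LatencyMap":
        """Affine map anchored at r = 1 (shortest healthy latency) and r = floor."""
        hi = 1.0 / (lat_at_ceiling + offset_min)
        lo = 1.0 / (lat_at_floor + offset_min)
        alpha = (hi - lo) / (1.0 - floor)
        beta = lo - floor * alpha
        return cls(alpha=alpha, beta=beta, offset_min=offset_min)

    @classmethod
    def narcolepsy(cls, offset_min: float = 10.0) -> "LatencyMap":
        return cls(alpha=1.0 / offset_min, beta=0.0, offset_min=offset_min)


@dataclass(frozen=True)
class FeatureConfig:
    """Detector settings for the four circadian features of the 24-h curve."""

    smooth_window_h: float = 2.0
    anz_clock_window: tuple[float, float] = (10.0, 18.0)
    wmz_clock_window: tuple[float, float] = (17.0, 23.0)
    morning_span_h: float = 4.0
    anz_min_prominence_frac: float = 0.02
    wmz_min_prominence_frac: float = 0.005
    boundary_margin_h: float = 1.0
    # during forced desynchrony the evening dip can fall inside a sleep
    # opportunity (an efficiency trough); FD-day analysis disables this
    wmz_require_wake: bool = True


# ---------------------------------------------------------------------------
# structured-text config round trip

_SECTION_TYPES = {
    "s_process": SParams,
    "r_process": RParams,
    "sc_process": SCParams,
    "latency_map": LatencyMap,
    "features": FeatureConfig,
}


def _build(section: str, payload: Mapping) -> object:
    cls = _SECTION_TYPES[section]
    payload = dict(payload)
    for key, value in payload.items():
        if isinstance(value, list):
            payload[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
    return cls(**payload)


def load_params(path: str | Path) -> dict[str, object]:
    """Read a flat key-value YAML config into parameter records.

    Unknown sections are returned as plain dicts so scenario settings can ride
    along in the same file.
    """
    with open(path, "r") as fh:
        doc = yaml.safe_load(fh) or {}
    out: dict[str, object] = {}
    for section, payload in doc.items():
        if section in _SECTION_TYPES and isinstance(payload, Mapping):
            out[section] = _build(section, payload)
        else:
            out[section] = payload
    return out


def save_params(params: Mapping[str, object], path: str | Path) -> None:
    doc = {}
    for section, value in params.items():
        if hasattr(value, "__dataclass_fields__"):
            doc[section] = asdict(value)
        else:
            doc[section] = value
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@lru_cache(maxsize=1)
def _default_doc() -> dict:
    text = resources.files("srsleep").joinpath("data/default_params.yaml").read_text()
    return yaml.safe_load(text)


def default_params() -> dict[str, object]:
    """Shipped default calibration (fresh record instances on every call)."""
    doc = _default_doc()
    out: dict[str, object] = {}
    for section, payload in doc.items():
        if section in _SECTION_TYPES and isinstance(payload, Mapping):
            out[section] = _build(section, payload)
        else:
            out[section] = payload
    return out
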