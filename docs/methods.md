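# Methods

## Model

Total sleep propensity is the product of two strictly positive drives,
`P(t) = S(t)·R(t)`, sampled on a uniform grid of decimal hours.

**Homeostat S.** Saturating exponentials with separate time constants for
buildup in wakefulness (`τᵢ`, default 18.2 h) and dissipation in sleep
(`τ_d`, default 4.2 h), bounded by asymptotes `UA = 1` and `LA = 0.05`
(arbitrary units; S never reaches zero).  These four constants are the
standard literature values for the two-process homeostat and are used
unchanged.  Within a wake or sleep segment S is evaluated in closed form
from the segment-start value, so prescribed-mode trajectories are exact and
independent of the sampling step; the step `dt` (default 0.1 h, 1/60 h for
the ultra-short protocol) only sets where the curve is sampled.
Simulations start at the entrained-cycle fixed point of S at wake-up
(closed form in `entrained_fixed_points`) unless `s_init` is given.

**Circadian REM drive R.** A phase-skewed raised cosine of clock time,

```
R(t) = r_min + A·((1 + cos ψ)/2)^k,   ψ = θ + s·(1 − cos θ),
θ = 2π(t − φ_R)/24,
```

with floor `r_min = 0.05`, amplitude `A = 0.95`, acrophase `φ_R = 05:00`,
shape exponent `k = 1` and skew `s = −0.6` as shipped defaults.  The skew
leaves the maximum at the acrophase but slows the post-peak decline and
sharpens and delays the trough (to ≈ 20:00 with the defaults).  R is
periodic with 24 h exactly (the clock argument is wrapped before the
cosine) and strictly positive.

The skew term is the one structural choice that was genuinely open: the
empirical REM-propensity curve this drive stands in for has never been
published in analytic form.  A systematic scan of the symmetric family
(`s = 0`, all other defaults varied ±20%) showed that no symmetric cosine
can simultaneously produce a dominant nocturnal peak and an afternoon
napping zone that survives 6-h delays of the preceding sleep: an early
acrophase (needed for the night peak) forces the afternoon decline of R to
be steep, which extinguishes the secondary peak by 3–4 h of delay.  The
asymmetry — broad morning/afternoon shoulder, sharp evening trough — is
also what the phenomenology implies verbally: the napping zone persists
into the afternoon while the wake-maintenance zone sits only a few hours
before habitual bedtime.

**Amplitude attenuation.** Forced desynchrony with severe sleep restriction
flattens the circadian modulation of R.  The attenuation scale multiplies
the modulation *about the circadian mean* (mesor): scale 1 is the full
curve, scale 0 a flat line at the mesor.  Pivoting about the mesor rather
than the floor is deliberate: the attenuated state is one of uniformly
*high* REM pressure (as in narcolepsy's ceiling), and a floor-pinned
attenuation would instead collapse R toward its minimum, making propensity
fall — the opposite of what severe restriction produces.  The profile is
piecewise linear in continuous days between anchor scales (1.0 at FD0, an
end scale at FD7, default 0.1) and constant beyond its endpoints.

**Classic S-C comparison.** The threshold model switches wake→sleep when S
reaches the upper threshold `H(t) = H̄ + H_a·sin(2π(t − φ_C)/24)` and
sleep→wake at the lower threshold L (same form; optional fixed 25%-weight
second-harmonic skew).  Crossing times are bracketed on the grid and
refined by Brent root-finding on the analytic segment, so switch times are
grid-independent to < 10⁻³ h.  Threshold pairs that cross anywhere on a
0.05-h clock grid are rejected at construction.  A wake phase whose
asymptote never reaches H completes with zero onsets and a `trapped` flag.

## Protocols

Schedules are ordered, non-overlapping, half-open sleep episodes
`[start, start + duration)` on a continuous hour axis (the onset sample is
asleep, the offset sample awake); episodes are clipped, never wrapped, at
the horizon.  The entrained builder places one night per 24-h day with the
time origin at habitual wake-up, so every analysis day runs wake-up to
wake-up.  The forced-desynchrony builder appends 28-h days after entrained
adaptation days, each with one sleep opportunity of `day_length·s/(s+w)`
hours at the end of the day's wake span (the within-day placement is not
specified by the protocol descriptions available; end-of-wake placement is
the reconstruction rule used here, stated so runs are reproducible).  The
narcolepsy actogram is rule-generated and synthetic: a fragmented night
(00:00–06:00 with two 30-min awakenings) plus 30-min naps at 10:00, 14:00
and 17:30.

The shift sweep displaces the nights *preceding* the analysis day while the
analysis day itself ends at the habitual bedtime — the question it answers
is how the phase of prior sleep reshapes the following day's landmarks.
The analysis window runs from 2 h before the (shifted) wake-up until the
habitual next wake-up, so it never spills into the following morning.

## Feature detection

The classifier smooths P with a centred 2-h moving average (shrinking
windows at the edges), finds interior extrema by sign changes of the first
difference (plateaus collapse to midpoints; kinds strictly alternate), and
classifies per analysis window:

- **nocturnal peak** — global maximum (flagged if the window contains no
  scheduled sleep);
- **ANZ** — largest local maximum with clock time in [10:00, 18:00] during
  scheduled wakefulness; *present* iff its topographic prominence is at
  least 2% of the window's global maximum (the explicit criterion that
  makes "the ANZ disappears" testable);
- **morning minimum** — lowest local minimum within 4 h after wake-up
  (search extended half a smoothing window before wake-up, since averaging
  displaces the dip slightly);
- **WMZ** — lowest local minimum with clock time in [17:00, 23:00] during
  wakefulness, at least 1 h from any episode boundary (edge-evoked
  homeostatic dips are not circadian landmarks), distinct from the morning
  minimum, with a small prominence floor (0.5% of the window maximum) as a
  noise guard.

All windows and fractions are configurable (`FeatureConfig`); feature
detection is invariant to uniform scaling of P (times unchanged,
prominences scale).  For per-FD-day tables the WMZ wake requirement is
dropped: when the sleep opportunity covers the early evening, the circadian
dip expresses within sleep (as an efficiency trough) rather than during
wakefulness.

## REM-latency transform and fits

Raw REM pressure is `1/(latency + c)` with offset `c = 10` min (guards
against division blow-up at sleep-onset-REM latencies).  Two rescalings
exist:

- **min-max** (`rem_latency_to_r` default): sample extremes map to
  `[r_min, 1]`.  Simple and assumption-free, but the sample extremes are
  order statistics inflated by noise, so it is kept for drive-curve
  construction only.
- **calibrated**: inverts the package's declared affine latency map
  `raw = α·r + β` (anchored so r = 1 ↔ 60 min and r = 0.05 ↔ 200 min),
  preserving absolute amplitude.  The fits use this scale.

`fit_r_cosinor` grid-searches the acrophase in 0.1-h steps and solves the
amplitude in closed form at each candidate (the model is linear in
amplitude once phase and shape are fixed) — deterministic and free of local
minima.  Floor, shape exponent and skew are held fixed.  The fit is
equivariant under clock rotation and recovers noiseless parameters to grid
resolution.

`fit_attenuation_endpoints` fits each anchor day with a *free intercept*
and takes the ratio of the modulation slopes: because attenuation pivots
about the mesor, only the modulation amplitude carries the scale, and a
floor-anchored fit would absorb the raised trough into its amplitude and
overestimate the end scale.

`fit_narcolepsy_r` handles the sleep-onset-REM regime (any latency below
15 min): latencies map through the saturating absolute transform
`r = c/(latency + c)` (zero latency → r = 1) and floor and amplitude are
both fitted under the ceiling constraint `r_min + A ≤ 1` (active-set: if
the unconstrained optimum violates the ceiling, the amplitude is re-solved
on the boundary).  Uniformly short latencies therefore force a high floor
and a small residual amplitude.  Inputs without any SOREM latency are
outside the regime and are delegated to the healthy cosinor fit.

## Synthetic data

The generators are pure functions of parameters and seed
(`numpy.random.default_rng`).

**REM latencies.** Clean latency = inverse latency map at `R(t)`;
multiplicative lognormal noise moment-matched so the minute-scale standard
deviation equals the requested value at each timepoint (latencies are
positive and right-skewed).  The default conditions for recovery checks are
48 observations (2 per hour over 24 h) at 15-min noise.

**Nap EEG-synchronization ramps.** Each 7-min nap of the ultra-short
protocol yields samples every 30 s on the 0–10 scale: starting fully
desynchronized (10) and decaying exponentially toward `10·(1 − P)` at rate
`P` per minute, where P is the propensity at nap start — sleepier naps
synchronize faster and deeper.  The decay-rate constant is a stand-in for
unpublished per-subject dynamics; the mapping between synchronization
units and propensity is declared, not derived.  Gaussian noise (default sd
0.5) is added per sample, clipped to [0, 10].  The reduction back to a
daily curve is `10 −` final sample per nap, placed at nap start, smoothed
with the 2-h moving average.  At zero noise the recovered curve's feature
classification matches the generating trajectory's (same presence flags,
times within the nap-sampling resolution).

What the generators do *not* emulate: between-subject variability, sleep
architecture within episodes, REM-cycle ultradian structure, and any light
or temperature pathway.  Passing tests therefore demonstrate internal
consistency of the model-transform-fit loop, not validity on real
polysomnography.

## Calibration of the shipped defaults

The S constants and the asymptotes are literature values and were not
touched.  The R shape (`φ_R = 5.0`, `s = −0.6`, `k = 1`, `A = 0.95`,
`r_min = 0.05`) is a single calibration chosen, once, by a grid scan so
that the entrained baseline shows all four landmarks with the nocturnal
peak dominant (secondary/primary ratio ≈ 0.73), the delay sweep loses the
ANZ beyond 6 h, the restricted FD run loses it at FD2, advances of 2–4 h
give comparable peaks, and the WMZ clock time stays within 0.1 h across
±4-h shifts.  The attenuation end scale (0.1) is the value at which the
FD7 wake-maintenance dip disappears on the restricted arm.  All of these
live in `src/srsleep/data/default_params.yaml`; none are hard-coded.

Problem sizes used throughout (3–4 simulated days per scenario, 7 FD days,
0.1-h sampling, 48-observation fits) are the scales of the corresponding
experimental protocols.

## Known limitations

- Under the linear FD0→FD7 attenuation, FD6 still retains ≈ 20% of the
  circadian modulation, and any residual modulation of a multiplicative
  interaction leaves a detectable evening dip: the wake-maintenance zone
  disappears at FD7 but is still detected on FD6.  Removing it on FD6 as
  well would require a nonlinear (front-loaded) attenuation course, which
  the linear-interpolation assumption deliberately avoids.
- The 28-h protocol re-aligns with the 24-h clock at FD6 (6·28 = 7·24), so
  afternoon maxima genuinely recur on late FD days in the simulation; the
  first disappearance (FD2) is the robust, reported quantity.
- The propensity scale is relative (arbitrary units); only ratios, times
  and presence/absence of features are meaningful across runs.
- The latency maps (affine healthy, saturating SOREM) are declared
  calibrations, not estimates from data; absolute amplitude recovery is
  relative to that declaration.
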