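# Shipped default calibration of the S.R sleep-propensity simulator.
# One file holds every tunable constant; operations never hard-code these.
# Drive levels are arbitrary units (a.u.), times decimal hours.

s_process:
  upper_asymptote: 1.0
  lower_asymptote: 0.05
  tau_rise: 18.2        # h, wake buildup time constant
  tau_fall: 4.2         # h, sleep dissipation time constant
  s_init: null          # null -> entrained fixed point at wake-up

r_process:
  floor: 0.05
  amplitude: 0.95
  acrophase: 5.0        # clock h of the REM-drive maximum
  period: 24.0
  shape_exponent: 1.0
  skew: -0.6            # slow post-peak decline, sharp trough near 20:00

sc_process:
  h_mean: 0.60
  h_amp: 0.10
  l_mean: 0.17
  l_amp: 0.10
  phase: 22.0
  skew_l: false

latency_map:
  alpha: 0.010025062656641603   # affine reciprocal-latency calibration
  beta: 0.004260651629072682    # anchors: r=1 -> 60 min, r=0.05 -> 200 min (offset 10)
  offset_min: 10.0

features:
  smooth_window_h: 2.0
  anz_clock_window: [10.0, 18.0]
  wmz_clock_window: [17.0, 23.0]
  morning_span_h: 4.0
  anz_min_prominence_frac: 0.02
  wmz_min_prominence_frac: 0.005
  boundary_margin_h: 1.0
  wmz_require_wake: true

engine:
  dt: 0.1                       # h, default sampling step
  attenuation_end_scale: 0.1    # FD7 circadian-amplitude scale, 1:5 arm

narcolepsy_r:
  floor: 0.85
  amplitude: 0.12
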