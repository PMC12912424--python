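"""A 2-h nap at 14:00 and its effect on the following night.

Two limiting cases: the sleeper falls asleep at the habitual midnight
anyway (shallower night, lower propensity throughout), or waits until
propensity regains the habitual onset level (later onset, shorter night).
"""
import numpy as np
import srsleep as sr

imm = sr.scenario_nap("immediate")
night = (imm.baseline.t >= 40.0) & (imm.baseline.t <= 48.0)
drop = imm.baseline.P[night] - imm.nap.P[night]

print("Immediate night onset after a 14:00-16:00 nap:")
print(f"  night propensity is below baseline at every sample; mean deficit "
      f"{drop.mean():.3f} a.u. (max {drop.max():.3f})")

dly = sr.scenario_nap("delayed")
delay_h = dly.onset_time - 40.0
print("Delayed-onset variant (sleep only once P regains the usual onset level):")
print(f"  habitual onset level P_ref = {dly.p_ref:.3f}")
print(f"  sleep onset postponed by {delay_h:.1f} h (to clock "
      f"{(24.0 + delay_h) % 24:.1f}:00), wake-up fixed at 08:00 -> night "
      f"shortened to {8.0 - delay_h:.1f} h")
print()
print("The nap discharges S; with R unchanged the product stays roughly")
print("parallel to baseline but lower — matching reports of reduced sleep")
print("quality, efficiency and duration after daytime napping.")
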