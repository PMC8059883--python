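"""Flicker magnitude functions of control versus degenerating rods.

Evaluates the two-stage linear-nonlinear model for the wild-type control and
the P23H knock-in parameter sets and prints where each magnitude function
peaks along the irradiance axis.  Faster recovery kinetics and a smaller
collecting area push the transgenic peak to brighter light.
"""

import numpy as np

from rodflick import StimulusSpec, flicker_magnitude, get_preset, peak_irradiance

ctl = get_preset("rho_wt_p23h_ctl")
tg = get_preset("rho_p23h")
stim = StimulusSpec(mean_irradiance=1250.0, contrast=0.75, frequency_hz=6.0)

print("6 Hz, 75% contrast flicker at 1250 R*/rod/s (mesopic):")
for preset in (ctl, tg):
    mag = flicker_magnitude(preset.rod, stim)
    peak = peak_irradiance(preset.rod, stim)
    print(f"  {preset.name:18s} magnitude {mag:7.2f} uV,"
          f" peak response at {peak:8.1f} R*/rod/s")

shift = (peak_irradiance(tg.rod, stim) / peak_irradiance(ctl.rod, stim))
print(f"rightward shift of the transgenic magnitude function: {shift:.2f}-fold")
print("-> at mesopic light the degenerating retina responds MORE to contrast,")
print("   because its compressive nonlinearity engages at brighter light.")
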