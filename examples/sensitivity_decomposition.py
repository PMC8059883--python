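"""Decomposing the loss of background-light sensitivity in degenerating rods.

Generates circulating-current suppression curves for the control and P23H
presets, fits the half-saturating background (I_50CS) of each, and splits the
measured fold-loss into the parts predicted by faster recovery kinetics and
by the smaller collecting area.
"""

import numpy as np

from rodflick import (
    circ_suppression,
    fit_i50cs,
    get_preset,
    make_suppression_curve,
    sensitivity_shift,
)

ctl = get_preset("rho_wt_p23h_ctl")
tg = get_preset("rho_p23h")
backgrounds = np.array([0.0] + list(np.logspace(1.5, 5.0, 9)))

i50 = {}
for preset in (ctl, tg):
    curve = make_suppression_curve(preset, backgrounds)
    fit = fit_i50cs(curve.backgrounds[1:], circ_suppression(curve)[1:])
    i50[preset.name] = fit.half_saturation
    print(f"{preset.name:18s} I_50CS = {fit.half_saturation:8.0f} R*/rod/s"
          f"  (R^2 = {fit.r_squared:.4f})")

measured = i50[tg.name] / i50[ctl.name]
decomp = sensitivity_shift(ctl.rod, tg.rod, fold_measured=measured)
print(f"measured fold-loss in I_50CS:    {measured:.2f}")
print(f"  kinetics fold (tau ratio):     {decomp.fold_kinetics:.2f}")
print(f"  collecting-area fold:          {decomp.fold_collecting_area:.2f}")
print(f"  predicted total (product):     {decomp.fold_total_predicted:.2f}")
print("-> faster recovery and shorter outer segments together account for")
print("   the measured desensitization of the rod circulating current.")
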