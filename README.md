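# rodflick

Quantitative analysis of rod-driven **temporal contrast sensitivity (TCS)**
in the degenerating mouse retina, for retinal electrophysiologists and
modellers working with flicker and flash electroretinograms (ERGs).

Mice carrying the P23H rhodopsin knock-in (a common cause of retinitis
pigmentosa) or a rhodopsin hemizygous deletion have rods that recover from
light **faster** than wild-type rods — and, counter-intuitively, show
*enhanced* sensitivity to flickering light at mesopic levels even while
their photoreceptors degenerate. This package implements the modelling and
estimation chain with which that enhancement is explained quantitatively.

## The model

The isolated (photoreceptor-driven) flicker ERG is modelled as a two-stage
linear–nonlinear cascade. A sinusoidal stimulus
`I(t) = I·[1 + C·sin(wt)]` (mean irradiance *I* in photons/µm²/s ≈ R\*/rod/s,
contrast *C*, `w = 2πf₀`) passes a first-order low-pass filter with time
constant τ,

```
β = (1/τ)·C / sqrt((1/τ)² + w²),        φ = −arctan(wτ),
```

and drives a static saturating nonlinearity

```
y(t) = K · x(t) / (x(t) + γ·EC₅₀),      x(t) = A·I·[1 + β·sin(wt + φ)],
```

with collecting area *A* (µm²), `γ = 1/(h₀τ)` the inverse response
integration area, and `K = K₀·f_ONL` an output scale proportional to the
surviving fraction of the outer nuclear layer. The half peak-to-trough
flicker magnitude has the closed form

```
Δy = K·δ·β·A·EC₅₀·I / [(1−β²)·δ²·A²·I² + 2·δ·A·EC₅₀·I + EC₅₀²],   δ = h₀τ,
```

which peaks at `I* = EC₅₀/(δ·A·√(1−β²))`. Between a control (C) and a
transgenic (T) genotype, the background irradiance that half-suppresses the
rod circulating current shifts by

```
I₅₀,T / I₅₀,C = (A_C/A_T) · (h₀C/h₀T) · (τ_C/τ_T),
```

i.e. a **collecting-area fold × amplification fold × kinetics fold** — the
decomposition at the heart of the analysis.

Around the model sit the standard estimators: Fourier fundamental magnitude
(F0) of flicker responses; TCS as the reciprocal of the contrast whose F0
crosses a 10 µV criterion on a log-log line; the Pepperberg dominant time
constant τ_D (slope of saturation time vs ln flash strength); the
Lamb–Pugh phototransduction amplification factor; hyperbolic fits of
circulating-current suppression (I₅₀CS) and flash intensity–response
(I₅₀f); and per-frequency maximum-likelihood fits of the model's single
free parameter h₀. Seeded synthetic-data generators invert each analysis
model so every estimator is testable without recorded data.

## Worked example

```python
import numpy as np
from rodflick import (get_preset, make_flash_family, pepperberg_tau,
                      make_suppression_curve, circ_suppression, fit_i50cs,
                      sensitivity_shift)

ctl, tg = get_preset("rho_wt_p23h_ctl"), get_preset("rho_p23h")

# dominant time constant from a saturating-flash family
fam = make_flash_family(ctl, np.logspace(2, 4, 6))
print(round(pepperberg_tau(fam).tau_d_s * 1e3, 1))   # 135.0 (ms)

# half-saturating background of circulating-current suppression
bg = np.array([0.0] + list(np.logspace(1.5, 5, 9)))
i50 = {}
for p in (ctl, tg):
    curve = make_suppression_curve(p, bg)
    i50[p.name] = fit_i50cs(curve.backgrounds[1:],
                            circ_suppression(curve)[1:]).half_saturation
print(round(i50[tg.name] / i50[ctl.name], 2))   # 4.07 (measured fold-loss)

d = sensitivity_shift(ctl.rod, tg.rod)
print(round(d.fold_kinetics, 2),                # 2.45 (faster recovery)
      round(d.fold_collecting_area, 2),         # 1.58 (shorter outer segments)
      round(d.fold_total_predicted, 2))         # 3.88 (predicted total)
```

The measured 4.07-fold desensitization of the rod circulating current is
accounted for almost entirely by the product of the kinetics fold (2.45)
and the collecting-area fold (1.58).

The `examples/` directory holds one short script per capability
(`python examples/pepperberg_tau.py`, …), and the `rodflick` CLI exposes
every stage on the shell:

```bash
rodflick compare --config comparison.yaml --out results/
rodflick stage tau_d --config inputs.yaml
rodflick simulate --preset rho_p23h --out data/ --seed 1
```

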