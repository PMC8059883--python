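# Methods

## Model

The package treats the photoreceptor-driven flicker ERG as a two-stage
linear–nonlinear (LN) cascade: a first-order exponential low-pass filter
(time constant τ, the rod's dominant recovery time constant) followed by a
static hyperbolic saturation (the compressive suppression of the rod
circulating current). For a sinusoidal drive of mean irradiance *I*,
contrast *C* and frequency f₀ the filter attenuates the modulation depth to
β = (1/τ)·C/√((1/τ)² + w²) with w = 2πf₀, and the output is
y(t) = K·x/(x + γEC₅₀) with x(t) = A·I·(1 + β sin(wt + φ)), γ = 1/(h₀τ).
The closed-form half peak-to-trough magnitude (see README) follows by
evaluating x/(x+c) at its extrema x = A·I(1 ± β); the identity is exact and
is asserted numerically over random parameter sweeps in the test suite.

Assumptions worth keeping in mind:

* a **single-stage** filter. Real rod responses attenuate high frequencies
  more steeply; a single stage under-attenuates, which is why fitted h₀
  values vary with frequency when the model is applied per frequency.
  Multi-stage (≥3 integrator) filters are deliberately out of scope.
* the filter phase φ = −arctan(wτ) is the standard first-order lag. Only
  magnitudes feed the downstream statistics; the phase matters only to the
  waveform generator.
* the nonlinearity's position is a **single irradiance scale**: the model
  predicts half-maximal steady output at I₅₀ = γEC₅₀/A, so the fold-shift
  between genotypes factorizes exactly into (A_C/A_T)·(h₀C/h₀T)·(τ_C/τ_T).
  The decomposition assumes control and transgenic retinas share EC₅₀ and
  (by default) h₀.

### Units

*I* and EC₅₀ are both expressed in photons/µm²/s, A in µm²; the term γEC₅₀
is treated as commensurate with A·I, with the dimensionless h₀ absorbing
the residual unit mismatch. Luminance→photoisomerization conversion is
config data, not a constant: named calibration contexts ship the in-vivo
rule (800 R\*/rod/s per scotopic cd/m², 4 mm² pupil), the 7× more sensitive
ex-vivo preparation, and the two empirical anchors for the green-LED rigs
(2 cd/m² ≈ 1250 and 70 cd/m² ≈ 1500 R\*/rod/s), because the 800·luminance
rule alone does not reproduce the latter two (photopic vs scotopic units of
the LED are not disambiguated by the available calibrations).

### Collecting area

The end-on collecting area is computed from rod geometry as
A = f·(πd²/4)·(1 − 10^(−ΔD·L))·q. With the control geometry (f = 1.3,
q = 0.63, d = 1.4 µm, L = 24 µm, ΔD = 0.019 od/µm) the formula gives
0.820 µm², whereas the published per-genotype tables list 0.87 µm² (and a
funneling factor of 1.2 elsewhere, giving 0.76 µm²). The *ratios* are
consistent (1.6-fold for a 24→12 µm shortening) even though the absolute
values are not. The package therefore computes areas from the formula *and*
accepts a direct area override in `RodParams`; the shipped presets carry
the published absolute values, and fold computations are insensitive to the
choice. Neither path is silently preferred.

## Parameters and presets

Four genotype presets (`rho_wt_p23h_ctl`, `rho_p23h`, `rho_wt_hemi_ctl`,
`rho_hemi`) carry the measured per-genotype model parameters: τ (0.135,
0.055, 0.138, 0.068 s), collecting area (0.87, 0.55, 0.87, 0.55 µm²),
f_ONL (1, 0.6, 1, 1), K₀ (750, 675, 1100, 990 µV) and a shared
EC₅₀ = 300 photons/µm²/s. K₀ additionally carries a per-frequency
multiplier map defaulting to {12 Hz: 0.6}. All presets use h₀ = 4, matching
the decomposition's equal-amplification assumption; the per-frequency
fitted transgenic values (6.3/3.3/1.5 and 6.9/3.8/1.0 at 3/6/12 Hz) ship in
`presets.FITTED_H0` for exploration. Preset auxiliaries drive the
generators: amplification factors 12.3/10.9 s⁻² for the two control lines
(the transgenic raw values 7.0/9.9 s⁻² are back-computed from their
area-adjusted estimates 11.1/15.7 s⁻² divided by the 1.58 area fold) and
I₅₀CS targets 2480/10100/1800/6000 R\*/rod/s.

## Estimators: numerical choices

* **Fundamental magnitude** is (2/N)·|Σ v·e^(−i2πf₀t)| over an integer
  number of periods; non-integer coverage is truncated with a warning.
  DC and harmonics are exactly rejected on integer windows.
* **Contrast threshold / TCS**: least-squares line on log₁₀F0 vs log₁₀C;
  the threshold is the crossing of log₁₀(10 µV). Thresholds needing more
  than one decade of extrapolation beyond the measured contrast range are
  refused (flagged, not a number) — measured series only reach 25%
  contrast, so deeper extrapolation is unsupported. The criterion and the
  cap are parameters.
* **Saturation time**: first downward crossing of the normalized response
  through the recovery level after the response maximum, by linear
  interpolation between samples. The default level 0.6 reads "recovery to
  ~60%" as *falling to* 0.6 of the plateau; the alternative reading
  (*recovered by* 60%, level 0.4) is one argument away. τ_D is the OLS
  slope of T_sat on ln(flash strength); the fit defaults to all saturated
  flashes and, if their line has R² < 0.95, falls back to the largest
  suffix of brightest flashes attaining it (the practice of restricting to
  the visually linear range, automated). A user-designated subset always
  wins.
* **Amplification factor**: joint least squares across dim flashes
  (≤100 R\*/rod), restricted to t < 75 ms and normalized amplitude < 0.2,
  with fits of R² ≤ 0.9 flagged as rejected. The default model is the full
  saturating activation form R = 1 − exp(−½·amp·φ·(t−t_eff)²), whose
  small-response limit is the familiar parabola R/φ = ½·amp·(t−t_eff)².
  The parabola itself is available (`model="parabola"`) but is biased
  ~5–10% low on responses approaching the 0.2 amplitude cutoff, because
  the true rise flattens; the saturating form is the package's default
  precisely so that generator→estimator recovery is exact.
* **Hyperbolic fits** (I₅₀CS and I₅₀f, Hill coefficient fixed at 1) use
  plain least squares with tight solver tolerances (scale equivariance
  holds to ~1e-6). Data that do not straddle half-saturation produce an
  ill-conditioned-fit warning. The two brightest in-vivo backgrounds
  (32 and 64 cd/m²) recruit cone responses and should be excluded upstream;
  `fit_i50cs` takes an exclusion threshold for this. i_circ = 1 − R/R_dark
  is clipped to [0, 1] with a warning — the small (<20%) dim-background
  facilitation of the a-wave is observed but not modelled.
* **h₀ fitting** maximizes a Gaussian iid likelihood of the residuals
  (equivalent to least squares; the residual noise model is not otherwise
  characterized, so the simplest MLE consistent with reported R²/RMSE is
  used). The search runs over log₁₀h₀ in (10⁻³, 10³) with eight bounded
  multi-start segments, making the result deterministic given the data.
  RMSE is reported with the sample-SD convention √(SS_res/(n−1)),
  switchable via `ddof`. K₀ (including the 0.6 multiplier at 12 Hz) is held
  fixed during fitting; frequencies are fit independently.
* **Line fits** everywhere are ordinary least squares; no robust losses.

## Synthetic-data generators

The generators emulate the statistical structure the estimators assume, so
each pair closes exactly on noiseless input:

* flicker traces are the LN waveform in µV plus iid Gaussian noise per
  trial, averaged over trials (effective sd shrinks as 1/√n_trials);
* contrast series follow M(C) = M(0.75)·(C/0.75)^s anchored to the model's
  75%-contrast magnitude, with exponent s ∈ [1, 2] defaulting to 1.5 — the
  mid-range of the log-log slopes observed in real series (1.35–1.75);
* flash families rise along 1 − exp(−½·amp·φ·(t−t_eff)²); flashes whose
  rise completes by the peak-time floor (0.13 s) count as saturating, hold
  their plateau until t_rec(φ) = T_ref + τ·ln(φ/φ_ref) (T_ref = 0.4 s,
  φ_ref = smallest saturating strength, both configurable), then decay
  exponentially (tail time constant 0.2 s). The saturation times therefore
  obey the Pepperberg law with slope exactly the preset τ. The exponential
  tail and the peak-time floor are modelling conveniences — only the
  early-phase rise and the saturation-time law are analysis-constrained —
  so dim-flash tail shapes and times-to-peak should not be read as
  physiological predictions;
* suppression curves decline hyperbolically, R(bg) = R_dark·i₅₀/(bg+i₅₀)
  scaled to a configurable dark amplitude (default 400 µV, arbitrary).

A seed is mandatory for any nonzero noise; identical inputs and seed give
byte-identical outputs (the pipeline's report files reproduce exactly).
What passing closed-loop tests show is that the estimators are correct and
unbiased under the assumed data structure; they do not certify behaviour
under real-data pathologies the generators omit (drift, correlated noise,
cone intrusion, non-exponential recovery).

## Problem sizes

Default analyses are desk scale: flash families of 6 saturating + 5 dim
flashes at 2 kHz, suppression curves of 10 backgrounds, magnitude functions
of 12 log-spaced irradiances, and replicate simulations of 100–500 fits in
the tests. These sizes make every estimator's sampling behaviour visible
(e.g. the 1/√n shrinkage of the τ_D standard deviation) while keeping the
whole suite fast.

## Known limitations

* The single-stage filter under-attenuates high frequencies; fitted h₀
  varies with frequency as a symptom. Per-frequency fits are supported,
  joint multi-frequency fits with a shared h₀ are not.
* No cone, bipolar or inner-retinal modelling; no rod–cone interactions.
* No a-/b-wave scoring of composite flash ERGs and no denoising beyond
  trial averaging.
* Real fitted magnitude functions at 3 Hz are known to fit poorly
  (single-stage filter); without the original traces this is noted, not
  modelled.
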