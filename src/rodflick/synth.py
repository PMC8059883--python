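"""Synthetic ERG data generators.

Each generator inverts the analysis model its estimator assumes, so every
generator/estimator pair forms a closed loop: on noiseless input the
estimator recovers the generating parameter exactly (to solver tolerance).

* :func:`make_flicker_trace` — the two-stage linear-nonlinear waveform in
  microvolts, with optional per-trial Gaussian noise averaged over trials.
* :func:`make_contrast_series` — power-law magnitude-vs-contrast data
  anchored to the model magnitude at 75% contrast (the log-log slope of real
  series runs ~1.35-1.75; the default exponent 1.5 sits mid-range).
* :func:`make_flash_family` — normalized flash responses rising along the
  saturating activation form 1 - exp(-1/2*amp*phi*(t - t_eff)^2); saturating
  flashes hold their plateau until t_rec(phi) = T_ref + tau*ln(phi/phi_ref)
  and then decay exponentially, so the saturation times obey the Pepperberg
  law with slope exactly the preset tau.  (The exponential tail is a
  modelling convenience: only the saturation-time law is constrained by the
  analysis.)
* :func:`make_suppression_curve` — saturating-flash a-wave amplitudes
  declining hyperbolically with background, half-suppressed at the preset
  I_50CS.

Any nonzero noise sd requires a seed; identical inputs and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .features import ContrastSeries, FlashFamily, SuppressionCurve, Trace
from .model import StimulusSpec, flicker_magnitude, flicker_waveform
from .presets import GenotypePreset

__all__ = [
    "NoiseSpec",
    "make_flicker_trace",
    "make_contrast_series",
    "make_flash_family",
    "make_suppression_curve",
]

#: rise value at the reference plateau end above which a flash counts as saturating
_SAT_RISE = 0.995


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: per-trial sd, seed, and trial count.

    Averaging ``n_trials`` independent trials divides the effective sd by
    sqrt(n_trials).  A seed is mandatory whenever sd > 0.
    """

    sd: float = 0.0
    seed: int | None = None
    n_trials: int = 1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InputError("noise sd must be >= 0")
        if self.n_trials < 1:
            raise InputError("n_trials must be >= 1")
        if self.sd > 0 and self.seed is None:
            raise InputError("a seed is required for nonzero noise")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def average_trials(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return clean.copy()
        trials = clean + rng.normal(0.0, self.sd, size=(self.n_trials,) + clean.shape)
        return trials.mean(axis=0)


_NO_NOISE = NoiseSpec()


def make_flicker_trace(
    preset: GenotypePreset,
    stim: StimulusSpec,
    noise: NoiseSpec = _NO_NOISE,
    duration_s: float = 2.0,
    rate_hz: float = 1000.0,
) -> Trace:
    """Flicker response trace in uV (model waveform + trial-averaged noise)."""
    if duration_s <= 0 or rate_hz <= 0:
        raise InputError("duration and sampling rate must be > 0")
    if duration_s * stim.frequency_hz < 1:
        raise InputError("duration must cover at least one stimulus period")
    t = np.arange(round(duration_s * rate_hz)) / rate_hz
    clean = flicker_waveform(preset.rod, stim, t)
    return Trace(t, noise.average_trials(clean, noise.rng()), stimulus=stim)


def make_contrast_series(
    preset: GenotypePreset,
    frequency_hz: float,
    mean_irradiance: float,
    contrasts: np.ndarray,
    slope_exponent: float = 1.5,
    noise: NoiseSpec = _NO_NOISE,
) -> ContrastSeries:
    """Power-law contrast series anchored at the model's 75%-contrast magnitude."""
    contrasts = np.asarray(contrasts, dtype=float)
    if contrasts.size == 0:
        raise InputError("empty contrast list")
    if not 1.0 <= slope_exponent <= 2.0:
        raise InputError("slope_exponent must lie in [1.0, 2.0]")
    anchor = flicker_magnitude(
        preset.rod, StimulusSpec(mean_irradiance, 0.75, frequency_hz)
    )
    mags = anchor * (contrasts / 0.75) ** slope_exponent
    mags = noise.average_trials(mags, noise.rng())
    return ContrastSeries(contrasts, np.clip(mags, 0.0, None),
                          frequency_hz, mean_irradiance)


def _flash_response(
    t: np.ndarray, phi: float, amp: float, t_eff: float,
    t_rec: float, recovery_tau: float,
) -> np.ndarray:
    rise = 1.0 - np.exp(-0.5 * amp * phi * np.clip(t - t_eff, 0.0, None) ** 2)
    out = np.where(t <= t_rec, rise, 0.0)
    peak = 1.0 - np.exp(-0.5 * amp * phi * max(t_rec - t_eff, 0.0) ** 2)
    decay = t > t_rec
    out[decay] = peak * np.exp(-(t[decay] - t_rec) / recovery_tau)
    return out


def make_flash_family(
    preset: GenotypePreset,
    flash_strengths: np.ndarray,
    noise: NoiseSpec = _NO_NOISE,
    rate_hz: float = 2000.0,
    duration_s: float | None = None,
) -> FlashFamily:
    """Normalized flash-response family whose T_sat obeys the Pepperberg law.

    The recovery onset of each saturating flash is
    ``t_rec(phi) = T_ref + tau*ln(phi/phi_ref)`` with ``phi_ref`` the
    smallest saturating strength (rise >= 0.995 by T_ref) unless the preset
    overrides it; dim flashes peak early and recover with the same
    exponential tail.  Slope of T_sat versus ln(phi) is exactly the preset's
    dominant time constant tau.
    """
    phi_arr = np.asarray(flash_strengths, dtype=float)
    if phi_arr.size == 0 or np.any(phi_arr <= 0) or np.any(np.diff(phi_arr) <= 0):
        raise InputError("flash strengths must be positive and strictly ascending")
    amp, t_eff = preset.amplification_s2, preset.t_eff_s
    tau = preset.rod.tau_s
    # a flash counts as saturating if its rise is complete by the peak-time floor
    rise_at_floor = 1.0 - np.exp(
        -0.5 * amp * phi_arr * (preset.t_floor_s - t_eff) ** 2
    )
    if preset.phi_ref is not None:
        phi_ref = preset.phi_ref
    else:
        sat = phi_arr[rise_at_floor >= _SAT_RISE]
        phi_ref = float(sat[0]) if sat.size else float(phi_arr[-1])
    if duration_s is None:
        t_rec_max = preset.t_ref_s + tau * np.log(max(phi_arr[-1] / phi_ref, 1.0))
        duration_s = float(t_rec_max + 6.0 * preset.recovery_tau_s)
    t = np.arange(round(duration_s * rate_hz)) / rate_hz
    rng = noise.rng()
    traces = []
    for phi in phi_arr:
        t_rec = max(preset.t_ref_s + tau * np.log(phi / phi_ref), preset.t_floor_s)
        clean = _flash_response(t, phi, amp, t_eff, t_rec, preset.recovery_tau_s)
        noisy = np.clip(noise.average_trials(clean, rng), None, 1.05)
        traces.append(Trace(t, noisy, stimulus=float(phi)))
    return FlashFamily(phi_arr, tuple(traces))


def make_suppression_curve(
    preset: GenotypePreset,
    backgrounds: np.ndarray,
    noise: NoiseSpec = _NO_NOISE,
) -> SuppressionCurve:
    """Saturating-flash a-wave amplitudes versus steady background (R*/rod/s)."""
    bg = np.asarray(backgrounds, dtype=float)
    if bg.size == 0 or bg[0] != 0:
        raise InputError("backgrounds must start at 0 (darkness)")
    clean = preset.r_dark_uv * (1.0 - bg / (bg + preset.i50cs_target))
    amps = noise.average_trials(clean, noise.rng())
    return SuppressionCurve(bg, np.clip(amps, 1e-9, None))
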