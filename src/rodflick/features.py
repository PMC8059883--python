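"""Estimators turning ERG traces and summary series into derived quantities.

Covers the analysis chain for rod-driven flicker and flash ERGs:

* :func:`fundamental_magnitude` — Fourier amplitude of a flicker response at
  the stimulus frequency (F0).
* :func:`contrast_threshold` / :func:`build_tcsf` — temporal contrast
  sensitivity from log-log magnitude-vs-contrast lines and a 10 uV criterion.
* :func:`saturation_time` / :func:`pepperberg_tau` — time in saturation of
  bright-flash responses and the dominant recovery time constant tau_D as the
  slope of T_sat against ln(flash strength).
* :func:`fit_amplification` — phototransduction activation gain from the
  early rising phase of dim-flash responses.
* :func:`circ_suppression` / :func:`fit_i50cs` — steady-state suppression of
  the rod circulating current by background light and its half-saturating
  background I_50CS.
* :func:`hill_fit` — half-saturating flash strength of the intensity-response
  relation (hyperbolic, Hill coefficient fixed at 1).
* :func:`time_to_peak` — response peak latency with parabolic refinement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import InputError, InsufficientDataError
from .model import StimulusSpec

__all__ = [
    "Trace",
    "ContrastSeries",
    "FlashFamily",
    "SuppressionCurve",
    "TCSF",
    "ThresholdResult",
    "SaturationResult",
    "PepperbergFit",
    "AmplificationFit",
    "HyperbolicFit",
    "PeakResult",
    "fundamental_magnitude",
    "contrast_threshold",
    "build_tcsf",
    "saturation_time",
    "pepperberg_regression",
    "pepperberg_tau",
    "fit_amplification",
    "circ_suppression",
    "fit_i50cs",
    "hill_fit",
    "time_to_peak",
]


@dataclass(frozen=True)
class Trace:
    """A single recorded or simulated response: uniform time grid + voltage.

    ``stimulus`` carries either a :class:`~rodflick.model.StimulusSpec` (for
    flicker trials) or a flash strength in R*/rod (for flash trials).
    """

    time_s: np.ndarray
    voltage_uv: np.ndarray
    stimulus: StimulusSpec | float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.voltage_uv, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "voltage_uv", v)
        if t.ndim != 1 or t.size < 2 or v.shape != t.shape:
            raise InputError("time and voltage must be matching 1-d arrays (n >= 2)")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InputError("time must be strictly increasing")
        if np.ptp(dt) > 1e-6 * dt.mean():
            raise InputError("time grid must be uniform to within 1 ppm")
        if not np.all(np.isfinite(v)):
            raise InputError("voltages must be finite")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time_s)))

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


def fundamental_magnitude(trace: Trace, frequency_hz: float) -> float:
    """Amplitude (uV) of the Fourier component of a trace at ``frequency_hz``.

    Computed as ``(2/N) * |sum v * exp(-i*2*pi*f0*t)|`` over an integer
    number of stimulus periods, which for a pure tone equals its amplitude
    (half the peak-to-peak excursion) and is insensitive to any DC offset.
    If the trace does not span an integer number of periods it is truncated
    to the largest whole number of periods, with a warning.
    """
    if frequency_hz <= 0:
        raise InputError("frequency must be > 0")
    n = trace.time_s.size
    dt = 1.0 / trace.sampling_rate_hz
    span = n * dt  # window length counting each sample's dt
    periods = span * frequency_hz
    n_whole = math.floor(periods + 1e-9)
    if n_whole < 1:
        raise InputError("trace must span at least one stimulus period")
    if abs(periods - round(periods)) > 1e-6 * periods:
        n_keep = int(round(n_whole / (frequency_hz * dt)))
        warnings.warn(
            f"trace spans {periods:.4f} periods; truncating to {n_whole}",
            stacklevel=2,
        )
    else:
        n_keep = n
    t = trace.time_s[:n_keep] - trace.time_s[0]
    v = trace.voltage_uv[:n_keep]
    phasor = np.exp(-2j * np.pi * frequency_hz * t)
    return float(2.0 / n_keep * abs(np.dot(v, phasor)))


@dataclass(frozen=True)
class ContrastSeries:
    """Fundamental magnitudes versus stimulus contrast at fixed frequency."""

    contrasts: np.ndarray
    magnitudes_uv: np.ndarray
    frequency_hz: float
    mean_irradiance: float

    def __post_init__(self) -> None:
        c = np.asarray(self.contrasts, dtype=float)
        m = np.asarray(self.magnitudes_uv, dtype=float)
        object.__setattr__(self, "contrasts", c)
        object.__setattr__(self, "magnitudes_uv", m)
        if c.size < 2 or m.shape != c.shape:
            raise InputError("need >= 2 (contrast, magnitude) pairs")
        if np.any(c <= 0) or np.any(c > 1):
            raise InputError("contrasts must lie in (0, 1]")
        if np.any(np.diff(c) <= 0):
            raise InputError("contrasts must be strictly ascending")
        if np.any(m < 0):
            raise InputError("magnitudes must be >= 0")


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a criterion-crossing threshold estimate on a log-log line."""

    threshold_contrast: float | None
    tcs: float | None
    slope: float
    intercept: float
    attained: bool
    reason: str = ""

    def __bool__(self) -> bool:  # truthiness == a threshold was found
        return self.attained


def contrast_threshold(
    series: ContrastSeries,
    criterion_uv: float = 10.0,
    max_extrapolation_decades: float = 1.0,
) -> ThresholdResult:
    """Threshold contrast and TCS from a log-log magnitude-vs-contrast line.

    A straight line is fit by least squares to log10(magnitude) against
    log10(contrast); the threshold contrast is where it crosses
    log10(criterion), and TCS is its reciprocal.  Thresholds that would
    require extrapolating more than ``max_extrapolation_decades`` beyond the
    measured contrast range are refused (flagged, not a number): the
    measurement only supports mild extrapolation below the dimmest tested
    contrast.
    """
    mask = series.magnitudes_uv > 0
    if mask.sum() < 2:
        raise InsufficientDataError("need >= 2 points with positive magnitude")
    log_c = np.log10(series.contrasts[mask])
    log_m = np.log10(series.magnitudes_uv[mask])
    slope, intercept = np.polyfit(log_c, log_m, 1)
    if slope <= 0:
        return ThresholdResult(None, None, slope, intercept, False, "non-positive slope")
    log_thr = (math.log10(criterion_uv) - intercept) / slope
    lo, hi = log_c.min(), log_c.max()
    if log_thr < lo - max_extrapolation_decades or log_thr > hi + max_extrapolation_decades:
        return ThresholdResult(
            None, None, slope, intercept, False,
            "criterion not reached within the extrapolation cap",
        )
    thr = 10.0**log_thr
    return ThresholdResult(thr, 1.0 / thr, slope, intercept, True)


@dataclass(frozen=True)
class TCSF:
    """Temporal contrast sensitivity function: TCS versus flicker frequency.

    Frequencies are ascending; series whose threshold was not attained
    propagate as NaN sensitivities.
    """

    frequencies_hz: np.ndarray
    sensitivities: np.ndarray
    thresholds: tuple[ThresholdResult, ...] = field(default=(), repr=False)


def build_tcsf(
    series_by_frequency: list[ContrastSeries], criterion_uv: float = 10.0
) -> TCSF:
    """Assemble a TCSF from per-frequency contrast series."""
    freqs = [s.frequency_hz for s in series_by_frequency]
    if len(set(freqs)) != len(freqs):
        raise InputError("duplicate frequencies in TCSF input")
    order = np.argsort(freqs)
    results = [contrast_threshold(series_by_frequency[i], criterion_uv) for i in order]
    sens = np.array([r.tcs if r.attained else np.nan for r in results])
    return TCSF(np.asarray(freqs, dtype=float)[order], sens, tuple(results))


@dataclass(frozen=True)
class SaturationResult:
    """Time in saturation of a normalized bright-flash response."""

    time_s: float
    saturated: bool
    reason: str = ""


def saturation_time(trace: Trace, recovery_level: float = 0.6) -> SaturationResult:
    """Time from flash onset to recovery through ``recovery_level``.

    The response is assumed normalized (plateau near 1) with the flash at
    t = 0.  T_sat is the first downward crossing of ``recovery_level`` after
    the response maximum, located by linear interpolation between samples.
    The default level 0.6 reads "recovery to ~60%" as the normalized response
    falling to 0.6 of its saturated plateau; pass a different level for the
    alternative reading (recovery *by* 60%, level 0.4).
    """
    v = trace.voltage_uv
    if v.max() < recovery_level:
        return SaturationResult(math.nan, False, "response never reaches the criterion level")
    i_peak = int(np.argmax(v))
    below = np.nonzero(v[i_peak:] < recovery_level)[0]
    if below.size == 0:
        return SaturationResult(math.nan, False, "response never recovers through the level")
    j = i_peak + below[0]  # first sample below the level, j >= 1
    t0, t1 = trace.time_s[j - 1], trace.time_s[j]
    v0, v1 = v[j - 1], v[j]
    t_cross = t0 + (v0 - recovery_level) / (v0 - v1) * (t1 - t0)
    return SaturationResult(float(t_cross), True)


@dataclass(frozen=True)
class FlashFamily:
    """A family of normalized flash responses at ascending strengths (R*/rod)."""

    flash_strengths: np.ndarray
    traces: tuple[Trace, ...]

    def __post_init__(self) -> None:
        phi = np.asarray(self.flash_strengths, dtype=float)
        object.__setattr__(self, "flash_strengths", phi)
        object.__setattr__(self, "traces", tuple(self.traces))
        if phi.size != len(self.traces):
            raise InputError("one trace per flash strength required")
        if np.any(phi <= 0) or np.any(np.diff(phi) <= 0):
            raise InputError("flash strengths must be positive, strictly ascending")
        for tr in self.traces:
            if tr.voltage_uv.max() > 1.05:
                raise InputError("normalized traces must peak at <= 1.05")

    def saturation_times(self, recovery_level: float = 0.6) -> list[SaturationResult]:
        return [saturation_time(tr, recovery_level) for tr in self.traces]

    def times_to_peak(self) -> list["PeakResult"]:
        return [time_to_peak(tr) for tr in self.traces]


@dataclass(frozen=True)
class PepperbergFit:
    """Dominant time constant from the T_sat versus ln(flash strength) line."""

    tau_d_s: float
    intercept_s: float
    r_squared: float
    n_used: int
    strengths_used: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


def pepperberg_regression(
    flash_strengths: np.ndarray, t_sat_s: np.ndarray
) -> PepperbergFit:
    """Ordinary least-squares line T_sat = tau_D * ln(phi) + const."""
    phi = np.asarray(flash_strengths, dtype=float)
    tsat = np.asarray(t_sat_s, dtype=float)
    if phi.size < 3:
        raise InsufficientDataError("need >= 3 saturated flashes for tau_D")
    x = np.log(phi)
    slope, intercept = np.polyfit(x, tsat, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((tsat - pred) ** 2))
    ss_tot = float(np.sum((tsat - tsat.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PepperbergFit(float(slope), float(intercept), r2, phi.size, phi)


def pepperberg_tau(
    family: FlashFamily,
    recovery_level: float = 0.6,
    use_strengths: np.ndarray | None = None,
    min_r_squared: float = 0.95,
) -> PepperbergFit:
    """Dominant time constant tau_D of photoresponse recovery from a family.

    Saturation times of the saturated flashes are regressed on the natural
    log of flash strength; the slope is tau_D.  ``use_strengths`` restricts
    the fit to a designated "linear range" subset (the standard practice is
    to pick it by eye); without one, if the full-family line has
    R^2 < ``min_r_squared`` the fit falls back to the largest suffix of
    brightest flashes attaining it.
    """
    sats = family.saturation_times(recovery_level)
    ok = np.array([s.saturated for s in sats])
    phi = family.flash_strengths[ok]
    tsat = np.array([s.time_s for s in sats])[ok]
    if use_strengths is not None:
        sel = np.isin(phi, np.asarray(use_strengths, dtype=float))
        phi, tsat = phi[sel], tsat[sel]
    fit = pepperberg_regression(phi, tsat)
    if use_strengths is None and fit.r_squared < min_r_squared:
        for start in range(1, phi.size - 2):
            trial = pepperberg_regression(phi[start:], tsat[start:])
            if trial.r_squared >= min_r_squared:
                return trial
    return fit


@dataclass(frozen=True)
class AmplificationFit:
    """Activation-phase gain of phototransduction from dim-flash rises."""

    amplification_s2: float
    t_eff_s: float
    r_squared: float
    n_points: int
    model: str
    accepted: bool  # practice is to reject fits with R^2 <= 0.9


def _rise_parabola(x, amp, t_eff):
    t, phi = x
    return 0.5 * amp * phi * np.clip(t - t_eff, 0.0, None) ** 2


def _rise_saturating(x, amp, t_eff):
    t, phi = x
    return 1.0 - np.exp(-0.5 * amp * phi * np.clip(t - t_eff, 0.0, None) ** 2)


def fit_amplification(
    family: FlashFamily,
    t_window_s: float = 0.075,
    amp_cutoff: float = 0.2,
    max_strength: float = 100.0,
    model: str = "saturating",
    area_ratio: float = 1.0,
) -> AmplificationFit:
    """Amplification factor (s^-2) from the early phase of dim-flash responses.

    Jointly fits all flashes with strength <= ``max_strength``, using only
    samples with t < ``t_window_s`` and normalized amplitude <
    ``amp_cutoff``.  The default model is the saturating activation form
    ``R = 1 - exp(-1/2 * amp * phi * (t - t_eff)^2)``, whose small-response
    limit is the parabola ``R/phi = 1/2 * amp * (t - t_eff)^2``; pass
    ``model="parabola"`` to fit the parabola directly (slightly biased low on
    responses approaching the cutoff, since the true rise flattens).
    ``area_ratio`` rescales the reported gain to account for a collecting-area
    difference between genotypes (ratio 1 leaves it unchanged).
    """
    ts, ys, ps = [], [], []
    for phi, tr in zip(family.flash_strengths, family.traces):
        if phi > max_strength:
            continue
        m = (tr.time_s < t_window_s) & (tr.voltage_uv < amp_cutoff) & (tr.time_s >= 0)
        ts.append(tr.time_s[m])
        ys.append(tr.voltage_uv[m])
        ps.append(np.full(int(m.sum()), phi))
    if not ts or sum(a.size for a in ts) < 4:
        raise InsufficientDataError("no dim-flash samples inside the fit window")
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    phi = np.concatenate(ps)
    func = {"saturating": _rise_saturating, "parabola": _rise_parabola}.get(model)
    if func is None:
        raise InputError(f"unknown amplification model {model!r}")
    # crude initial gain from the brightest dim flash's latest usable sample
    i0 = int(np.argmax(y))
    amp0 = max(2.0 * y[i0] / (phi[i0] * max(t[i0], 1e-4) ** 2), 1.0)
    popt, _ = curve_fit(func, (t, phi), y, p0=[amp0, 0.003], maxfev=20000)
    pred = func((t, phi), *popt)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AmplificationFit(
        amplification_s2=float(popt[0]) * area_ratio,
        t_eff_s=float(popt[1]),
        r_squared=r2,
        n_points=t.size,
        model=model,
        accepted=r2 > 0.9,
    )


@dataclass(frozen=True)
class SuppressionCurve:
    """Saturating-flash a-wave amplitude versus steady background intensity.

    The first background must be 0 (darkness); its amplitude R_dark
    normalizes the rest.
    """

    backgrounds: np.ndarray  # R*/rod/s, ascending, first entry 0
    awave_amplitudes_uv: np.ndarray

    def __post_init__(self) -> None:
        bg = np.asarray(self.backgrounds, dtype=float)
        r = np.asarray(self.awave_amplitudes_uv, dtype=float)
        object.__setattr__(self, "backgrounds", bg)
        object.__setattr__(self, "awave_amplitudes_uv", r)
        if bg.size < 2 or r.shape != bg.shape:
            raise InputError("need matching backgrounds and amplitudes (n >= 2)")
        if bg[0] != 0:
            raise InputError("first background must be 0 (darkness)")
        if np.any(np.diff(bg) <= 0):
            raise InputError("backgrounds must be strictly ascending")
        if r[0] <= 0:
            raise InputError("dark a-wave amplitude must be > 0")

    @property
    def r_dark_uv(self) -> float:
        return float(self.awave_amplitudes_uv[0])


def circ_suppression(curve: SuppressionCurve) -> np.ndarray:
    """Fractional suppression of circulating current: 1 - R(bg)/R_dark.

    Clipped to [0, 1] (with a warning): dim backgrounds can transiently
    *increase* the a-wave by <20%, which this analysis does not model.
    """
    i_circ = 1.0 - curve.awave_amplitudes_uv / curve.r_dark_uv
    if np.any(i_circ < 0) or np.any(i_circ > 1):
        warnings.warn("i_circ values outside [0, 1] were clipped", stacklevel=2)
    return np.clip(i_circ, 0.0, 1.0)


@dataclass(frozen=True)
class HyperbolicFit:
    """Half-saturation constant of a hyperbolic (Hill coefficient 1) fit."""

    half_saturation: float
    r_squared: float
    n_points: int
    well_conditioned: bool


def _fit_hyperbolic(x: np.ndarray, y: np.ndarray, what: str) -> HyperbolicFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise InsufficientDataError(f"need >= 4 points for the {what} fit")
    span_ok = bool(np.any(y < 0.5) and np.any(y > 0.5))
    if not span_ok:
        warnings.warn(
            f"{what} fit is ill-conditioned: data do not straddle half-saturation",
            stacklevel=3,
        )
    if np.all(y < 1e-9) or np.all(y > 1 - 1e-9):
        warnings.warn(f"{what} fit is degenerate (flat data)", stacklevel=3)
    pos = x[x > 0]
    x50_0 = float(np.median(pos)) if pos.size else 1.0
    popt, _ = curve_fit(
        lambda xx, x50: xx / (xx + x50), x, y, p0=[x50_0],
        bounds=(1e-12, np.inf), maxfev=20000,
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    pred = x / (x + popt[0])
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HyperbolicFit(float(popt[0]), r2, x.size, span_ok)


def fit_i50cs(
    backgrounds: np.ndarray,
    i_circ: np.ndarray,
    exclude_backgrounds_above: float | None = None,
) -> HyperbolicFit:
    """Half-saturating background I_50CS from the suppression curve.

    Least-squares fit of ``i_circ = I/(I + I_50CS)``.  Points at backgrounds
    above ``exclude_backgrounds_above`` can be dropped (the brightest
    backgrounds recruit cone responses and depart from the rod asymptote).
    """
    bg = np.asarray(backgrounds, dtype=float)
    ic = np.asarray(i_circ, dtype=float)
    if exclude_backgrounds_above is not None:
        keep = bg <= exclude_backgrounds_above
        bg, ic = bg[keep], ic[keep]
    return _fit_hyperbolic(bg, ic, "I_50CS")


def hill_fit(flash_strengths: np.ndarray, normalized_amplitudes: np.ndarray) -> HyperbolicFit:
    """Half-saturating flash strength I_50f (Hill coefficient fixed at 1)."""
    return _fit_hyperbolic(flash_strengths, normalized_amplitudes, "I_50f")


@dataclass(frozen=True)
class PeakResult:
    """Peak time of a single-flash response (parabolically refined)."""

    time_s: float
    defined: bool
    reason: str = ""


def time_to_peak(trace: Trace) -> PeakResult:
    """Time of the response maximum, refined by a parabola through the three
    samples around the discrete argmax.  Flat traces or maxima on the window
    boundary give an undefined-peak flag."""
    v = trace.voltage_uv
    if np.ptp(v) < 1e-12:
        return PeakResult(math.nan, False, "flat trace")
    i = int(np.argmax(v))
    if i == 0 or i == v.size - 1:
        return PeakResult(math.nan, False, "maximum on the window boundary")
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    dt = trace.time_s[i] - trace.time_s[i - 1]
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return PeakResult(float(trace.time_s[i] + offset * dt), True)
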