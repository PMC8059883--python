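"""Two-stage linear-nonlinear model of rod-driven flicker responses.

The model treats the isolated (photoreceptor-driven) flicker ERG as a
first-order low-pass linear filter followed by a static saturating
nonlinearity.  A sinusoidal stimulus of mean irradiance ``I`` (photons/um^2/s,
equivalently R*/rod/s for unit collecting area), contrast ``C`` and frequency
``f0`` drives a rod with collecting area ``A`` (um^2).  The filter attenuates
the modulation by

    beta = (1/tau) * C / sqrt((1/tau)^2 + w^2),      w = 2*pi*f0,

and the steady-state output is

    y(t) = K * x(t) / (x(t) + gamma*EC50),
    x(t) = A*I * (1 + beta*sin(w*t + phase)),

with ``gamma = 1/(h0*tau)`` the inverse response-integration area, ``h0`` a
dimensionless sensitivity scale, and ``K = K0*f_ONL`` an output scale
proportional to the surviving fraction of the outer nuclear layer.  The half
peak-to-trough excursion of y(t) over one period has the closed form
implemented by :func:`flicker_magnitude`; its argmax over irradiance is
:func:`peak_irradiance`.

Between two parameter sets (a control and a test/transgenic genotype), the
irradiance producing half-maximal steady suppression shifts by the product of
a kinetics fold (tau ratio), a collecting-area fold, and an amplification
fold (h0 ratio); :func:`sensitivity_shift` computes that decomposition.

Unit convention: ``I`` and ``EC50`` are both in photons/um^2/s and ``A`` in
um^2; the term ``gamma*EC50`` is treated as commensurate with ``A*I`` (the
dimensionless ``h0`` absorbs the residual unit mismatch).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError, InvalidGeometryError, InvalidParameterError

__all__ = [
    "RodGeometry",
    "RodParams",
    "StimulusSpec",
    "SensitivityDecomposition",
    "CalibrationContext",
    "CALIBRATION_CONTEXTS",
    "collecting_area",
    "filter_attenuation",
    "steady_state_output",
    "half_max_irradiance",
    "flicker_waveform",
    "flicker_magnitude",
    "peak_irradiance",
    "sensitivity_shift",
    "predicted_test_irradiance",
    "luminance_to_rate",
]


@dataclass(frozen=True)
class RodGeometry:
    """Geometry and optics of a rod outer segment, for the end-on collecting area.

    Parameters
    ----------
    funneling_factor
        Light funneling by the inner segment (dimensionless, > 0).
    quantum_efficiency
        Probability that an absorbed photon isomerizes rhodopsin (0-1].
    outer_segment_length_um, outer_segment_diameter_um
        Outer segment length and diameter in micrometres.
    specific_axial_density
        Specific axial pigment density in optical-density units per um (>= 0).
    """

    funneling_factor: float
    quantum_efficiency: float
    outer_segment_length_um: float
    outer_segment_diameter_um: float
    specific_axial_density: float

    def __post_init__(self) -> None:
        if self.outer_segment_length_um <= 0 or self.outer_segment_diameter_um <= 0:
            raise InvalidGeometryError(
                "outer segment length and diameter must be strictly positive"
            )
        if self.funneling_factor <= 0:
            raise InvalidGeometryError("funneling_factor must be strictly positive")
        if not 0 < self.quantum_efficiency <= 1:
            raise InvalidGeometryError("quantum_efficiency must lie in (0, 1]")
        if self.specific_axial_density < 0:
            raise InvalidGeometryError("specific_axial_density must be >= 0")


def collecting_area(geom: RodGeometry) -> float:
    """End-on rod collecting area in um^2.

    ``A = f * (pi d^2 / 4) * (1 - 10^(-dD * L)) * q``: the geometric cross
    section, funneled by the inner segment, times the axial absorption
    probability, times the quantum efficiency.  Strictly increasing in every
    field (zero pigment density gives zero area).
    """
    absorbed = 1.0 - 10.0 ** (
        -geom.specific_axial_density * geom.outer_segment_length_um
    )
    cross_section = math.pi * geom.outer_segment_diameter_um**2 / 4.0
    return geom.funneling_factor * cross_section * absorbed * geom.quantum_efficiency


@dataclass(frozen=True)
class RodParams:
    """Per-genotype parameter set of the linear-nonlinear flicker model.

    ``collecting_area_um2`` may be supplied directly (e.g. a published value)
    or computed from a :class:`RodGeometry` via :func:`collecting_area`;
    neither path is preferred.  ``k0_frequency_multipliers`` holds
    per-frequency output-scale corrections (default: 0.6 at 12 Hz).
    """

    tau_s: float
    h0: float
    collecting_area_um2: float
    ec50: float
    f_onl: float = 1.0
    k0: float = 1.0
    genotype_label: str = ""
    k0_frequency_multipliers: Mapping[float, float] = field(
        default_factory=lambda: {12.0: 0.6}
    )

    def __post_init__(self) -> None:
        for name in ("tau_s", "h0", "collecting_area_um2", "ec50", "k0"):
            if getattr(self, name) <= 0 or not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite and > 0")
        if not 0 < self.f_onl <= 1:
            raise InvalidParameterError("f_onl must lie in (0, 1]")

    @property
    def gamma(self) -> float:
        """Inverse response-integration area, 1/(h0*tau)."""
        return 1.0 / (self.h0 * self.tau_s)

    @property
    def delta(self) -> float:
        """Response integration area, h0*tau."""
        return self.h0 * self.tau_s

    def scaling(self, frequency_hz: float | None = None) -> float:
        """Output scale K = K0 * f_ONL, with any per-frequency multiplier."""
        mult = 1.0
        if frequency_hz is not None:
            for f, m in self.k0_frequency_multipliers.items():
                if math.isclose(f, frequency_hz, rel_tol=1e-9):
                    mult = m
                    break
        return self.k0 * self.f_onl * mult

    def with_h0(self, h0: float) -> "RodParams":
        return replace(self, h0=h0)


@dataclass(frozen=True)
class StimulusSpec:
    """Sinusoidal flicker stimulus: mean irradiance, contrast, frequency."""

    mean_irradiance: float
    contrast: float
    frequency_hz: float

    def __post_init__(self) -> None:
        if self.mean_irradiance < 0:
            raise InvalidParameterError("mean_irradiance must be >= 0")
        if not 0 <= self.contrast <= 1:
            raise InvalidParameterError("contrast must lie in [0, 1]")
        if self.frequency_hz <= 0:
            raise InvalidParameterError("frequency_hz must be > 0")

    @property
    def angular_frequency(self) -> float:
        return 2.0 * math.pi * self.frequency_hz


def filter_attenuation(params: RodParams, stim: StimulusSpec) -> tuple[float, float]:
    """Attenuation (beta) and phase (rad) of the first-order linear filter.

    ``beta = a*C/sqrt(a^2 + w^2)`` with rate ``a = 1/tau``; the phase is the
    standard first-order low-pass lag ``-arctan(w*tau)``.  ``0 <= beta <= C``;
    only the magnitude feeds downstream summary statistics.
    """
    a = 1.0 / params.tau_s
    w = stim.angular_frequency
    beta = a * stim.contrast / math.hypot(a, w)
    phase = -math.atan(w * params.tau_s)
    return beta, phase


def steady_state_output(
    params: RodParams, irradiance: float, frequency_hz: float | None = None
) -> float:
    """Steady-state (zero-contrast) output K*(A*I)/(A*I + gamma*EC50).

    Monotone increasing in irradiance, bounded in [0, K); half-maximal at
    :func:`half_max_irradiance`.
    """
    if irradiance < 0:
        raise InvalidParameterError("irradiance must be >= 0")
    x = params.collecting_area_um2 * irradiance
    return params.scaling(frequency_hz) * x / (x + params.gamma * params.ec50)


def half_max_irradiance(params: RodParams) -> float:
    """Irradiance eliciting a half-maximal steady-state output: gamma*EC50/A."""
    return params.gamma * params.ec50 / params.collecting_area_um2


def flicker_waveform(
    params: RodParams, stim: StimulusSpec, t: np.ndarray
) -> np.ndarray:
    """Steady-state response waveform y(t) to sinusoidal flicker.

    ``y(t) = K * x(t)/(x(t) + gamma*EC50)`` with
    ``x(t) = A*I*(1 + beta*sin(w*t + phase))``.  Bounded in [0, K), periodic
    with period 1/f0.  A zero-irradiance stimulus with nonzero contrast is
    degenerate and returns an all-zero series with a warning.
    """
    t = np.asarray(t, dtype=float)
    if stim.mean_irradiance == 0.0:
        if stim.contrast > 0:
            warnings.warn(
                "zero mean irradiance with nonzero contrast: degenerate stimulus",
                stacklevel=2,
            )
        return np.zeros_like(t)
    beta, phase = filter_attenuation(params, stim)
    x = (
        params.collecting_area_um2
        * stim.mean_irradiance
        * (1.0 + beta * np.sin(stim.angular_frequency * t + phase))
    )
    return params.scaling(stim.frequency_hz) * x / (x + params.gamma * params.ec50)


def flicker_magnitude(params: RodParams, stim: StimulusSpec) -> float:
    """Half peak-to-trough magnitude of the flicker response (units of K).

    Closed form
    ``K*delta*beta*A*EC50*I / ((1-beta^2)*delta^2*A^2*I^2 + 2*delta*A*EC50*I + EC50^2)``,
    which equals the analytic half peak-to-trough of :func:`flicker_waveform`.
    Vanishes as I -> 0 and I -> inf with a single interior maximum at
    :func:`peak_irradiance`.
    """
    beta, _ = filter_attenuation(params, stim)
    a_i = params.collecting_area_um2 * stim.mean_irradiance
    delta = params.delta
    num = params.scaling(stim.frequency_hz) * delta * beta * params.ec50 * a_i
    den = (
        (1.0 - beta**2) * delta**2 * a_i**2
        + 2.0 * delta * params.ec50 * a_i
        + params.ec50**2
    )
    return num / den


def peak_irradiance(params: RodParams, stim: StimulusSpec) -> float:
    """Irradiance maximizing :func:`flicker_magnitude`: EC50/(delta*A*sqrt(1-beta^2)).

    Decreasing in collecting area and in delta = h0*tau; requires beta < 1
    (always true for contrast <= 1 at any nonzero frequency).
    """
    beta, _ = filter_attenuation(params, stim)
    if beta >= 1.0:
        raise InvalidParameterError("filter attenuation beta must be < 1")
    return params.ec50 / (
        params.delta * params.collecting_area_um2 * math.sqrt(1.0 - beta**2)
    )


@dataclass(frozen=True)
class SensitivityDecomposition:
    """Fold-shift of half-suppression irradiance split into its components.

    The predicted total is the product of the kinetics fold (tau_C/tau_T),
    the collecting-area fold (A_C/A_T) and the amplification fold
    (h0_C/h0_T); ``fold_measured`` optionally carries the ratio of fitted
    half-saturating backgrounds (I_50CS, test/control) for comparison.
    """

    fold_kinetics: float
    fold_collecting_area: float
    fold_amplification: float = 1.0
    fold_measured: float | None = None

    @property
    def fold_total_predicted(self) -> float:
        return self.fold_kinetics * self.fold_collecting_area * self.fold_amplification


def sensitivity_shift(
    control: RodParams, test: RodParams, fold_measured: float | None = None
) -> SensitivityDecomposition:
    """Decompose the predicted control->test sensitivity shift into folds."""
    return SensitivityDecomposition(
        fold_kinetics=control.tau_s / test.tau_s,
        fold_collecting_area=control.collecting_area_um2 / test.collecting_area_um2,
        fold_amplification=control.h0 / test.h0,
        fold_measured=fold_measured,
    )


def predicted_test_irradiance(
    control: RodParams, test: RodParams, control_irradiance: float
) -> float:
    """Steady irradiance suppressing the test genotype's circulating current
    as much as ``control_irradiance`` suppresses the control's."""
    if control_irradiance < 0:
        raise InvalidParameterError("control_irradiance must be >= 0")
    return sensitivity_shift(control, test).fold_total_predicted * control_irradiance


@dataclass(frozen=True)
class CalibrationContext:
    """Named luminance -> photoisomerization-rate conversion.

    ``rstar_per_cd_m2`` is the photoisomerization rate (R*/rod/s) elicited in
    control rods by 1 cd/m^2 under this recording configuration.
    """

    name: str
    rstar_per_cd_m2: float


#: Shipped calibration anchors.  The in-vivo rule is 800 R*/rod/s per scotopic
#: cd/m^2 (4 mm^2 pupil); the ex-vivo preparation is ~7x more sensitive.  The
#: flicker-ERG and optomotor anchors are empirical (green LED, photopic units):
#: 2 cd/m^2 ~ 1250 and 70 cd/m^2 ~ 1500 R*/rod/s respectively.
CALIBRATION_CONTEXTS: dict[str, CalibrationContext] = {
    "in_vivo": CalibrationContext("in_vivo", 800.0),
    "ex_vivo": CalibrationContext("ex_vivo", 7.0 * 800.0),
    "flicker_erg_2cdm2": CalibrationContext("flicker_erg_2cdm2", 1250.0 / 2.0),
    "optomotor_70cdm2": CalibrationContext("optomotor_70cdm2", 1500.0 / 70.0),
}


def luminance_to_rate(
    luminance_cd_m2: float, context: str | CalibrationContext = "in_vivo"
) -> float:
    """Convert a luminance (cd/m^2) to a photoisomerization rate (R*/rod/s)."""
    if luminance_cd_m2 < 0:
        raise InvalidParameterError("luminance must be >= 0")
    if isinstance(context, str):
        try:
            context = CALIBRATION_CONTEXTS[context]
        except KeyError:
            raise ConfigurationError(
                f"unknown calibration context {context!r}; "
                f"known: {sorted(CALIBRATION_CONTEXTS)}"
            ) from None
    return context.rstar_per_cd_m2 * luminance_cd_m2
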