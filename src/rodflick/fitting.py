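"""Maximum-likelihood fitting of the model's single free parameter h0.

All fixed parameters (tau, collecting area, EC50, f_ONL, K0) come from
measurement; the sensitivity scale h0 is fit per frequency to the fundamental
magnitude versus mean-irradiance data.  Residuals are modelled as iid
Gaussian, so the MLE coincides with least squares; goodness of fit is
reported as R^2 and the RMSE computed as the sample SD of the residuals
(denominator n - 1, switchable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import InputError
from .model import RodParams, StimulusSpec, flicker_magnitude

__all__ = ["MagnitudeFunction", "FitResult", "fit_h0", "evaluate_fit"]


@dataclass(frozen=True)
class MagnitudeFunction:
    """Fundamental flicker magnitude versus mean irradiance at fixed
    frequency and contrast."""

    irradiances: np.ndarray  # R*/rod/s, ascending
    magnitudes_uv: np.ndarray
    frequency_hz: float
    contrast: float
    genotype_label: str = ""

    def __post_init__(self) -> None:
        i = np.asarray(self.irradiances, dtype=float)
        m = np.asarray(self.magnitudes_uv, dtype=float)
        object.__setattr__(self, "irradiances", i)
        object.__setattr__(self, "magnitudes_uv", m)
        if i.size < 4 or m.shape != i.shape:
            raise InputError("need >= 4 (irradiance, magnitude) pairs")
        if np.any(np.diff(i) <= 0):
            raise InputError("irradiances must be strictly ascending")
        if np.any(m < 0):
            raise InputError("magnitudes must be >= 0")


@dataclass(frozen=True)
class FitResult:
    h0: float
    r_squared: float
    rmse: float
    converged: bool
    n_points: int


def _predict(data: MagnitudeFunction, params: RodParams) -> np.ndarray:
    return np.array(
        [
            flicker_magnitude(
                params, StimulusSpec(i, data.contrast, data.frequency_hz)
            )
            for i in data.irradiances
        ]
    )


def evaluate_fit(
    data: MagnitudeFunction, params: RodParams, ddof: int = 1
) -> tuple[float, float]:
    """R^2 and RMSE of the model prediction against measured magnitudes.

    RMSE uses the sample-SD convention sqrt(SS_res/(n - ddof)), ddof=1 by
    default.  Constant data leave R^2 undefined (NaN, with a warning).
    """
    pred = _predict(data, params)
    resid = data.magnitudes_uv - pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((data.magnitudes_uv - data.magnitudes_uv.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("constant data: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / (data.irradiances.size - ddof)))
    return r2, rmse


def fit_h0(
    data: MagnitudeFunction,
    fixed: RodParams,
    bounds: tuple[float, float] = (1e-3, 1e3),
    n_starts: int = 8,
) -> FitResult:
    """Fit h0 by Gaussian maximum likelihood (equivalently least squares).

    The search is over log10(h0) within ``bounds``, with a multi-start
    bounded scalar optimization (the SSE in h0 can be multimodal at coarse
    scales).  The h0 stored in ``fixed`` is ignored; all other parameters,
    including the 12 Hz K0 multiplier, are held fixed.  Non-convergence is
    flagged, never silent.
    """
    y = data.magnitudes_uv

    def sse_log(lh: float) -> float:
        pred = _predict(data, fixed.with_h0(10.0**lh))
        return float(np.sum((y - pred) ** 2))

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    edges = np.linspace(lo, hi, n_starts + 1)
    best, converged = None, False
    for a, b in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(sse_log, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-10})
        if best is None or res.fun < best.fun:
            best, converged = res, bool(res.success)
    h0_hat = 10.0**best.x
    r2, rmse = evaluate_fit(data, fixed.with_h0(h0_hat))
    return FitResult(float(h0_hat), r2, rmse, converged, data.irradiances.size)
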