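"""End-to-end genotype comparison: kinetics, sensitivity, and decomposition.

:func:`run_compare` reproduces the genotype-comparison analysis in one call:
for a control and a test genotype it estimates the dominant recovery time
constant (Pepperberg regression on a saturating-flash family), the
amplification factor (dim-flash rise fit), the Hill half-saturating flash
strength, the half-saturating background of circulating-current suppression
(I_50CS), and the per-frequency model sensitivity h0; it then decomposes the
control-to-test sensitivity shift into kinetics, collecting-area and
amplification folds and compares the predicted total with the measured
I_50CS fold.

Inputs are either shipped genotype presets (synthetic data generated on the
fly, seeded through the config) or delimited-text files produced by this
package or by external acquisition.  Every run can write its intermediate
tables, a resolved copy of the configuration, and a YAML report.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as rio
from .exceptions import ConfigurationError
from .features import (
    AmplificationFit,
    FlashFamily,
    HyperbolicFit,
    PepperbergFit,
    SuppressionCurve,
    circ_suppression,
    fit_amplification,
    fit_i50cs,
    hill_fit,
    pepperberg_tau,
)
from .fitting import FitResult, MagnitudeFunction, fit_h0
from .model import SensitivityDecomposition, StimulusSpec, flicker_magnitude, sensitivity_shift
from .presets import GenotypePreset, get_preset
from .synth import NoiseSpec, make_flash_family, make_suppression_curve

__all__ = ["ComparisonReport", "GenotypeAnalysis", "run_compare", "run_stage", "STAGES"]

log = logging.getLogger("rodflick")

_DEFAULTS: dict[str, Any] = {
    "contrast": 0.75,
    "frequencies_hz": [3.0, 6.0, 12.0],
    "n_irradiances": 12,
    "irradiance_range": [10.0, 1e5],
    "flash_strengths_sat": list(np.logspace(2, 4, 6)),
    "flash_strengths_dim": [1.0, 3.0, 10.0, 30.0, 100.0],
    "backgrounds": [0.0] + list(np.logspace(1.5, 4.5, 9)),
    "noise_sd": 0.0,
    "seed": 0,
}


@dataclass(frozen=True)
class GenotypeAnalysis:
    """All per-genotype fitted quantities with their diagnostics."""

    preset: GenotypePreset
    tau_d: PepperbergFit
    amplification: AmplificationFit
    hill: HyperbolicFit
    i50cs: HyperbolicFit
    h0_by_frequency: dict[float, FitResult]

    def summary(self) -> dict[str, Any]:
        return {
            "genotype": self.preset.name,
            "tau_d_ms": round(self.tau_d.tau_d_s * 1e3, 3),
            "tau_d_r_squared": round(self.tau_d.r_squared, 4),
            "amplification_s2": round(self.amplification.amplification_s2, 3),
            "amplification_r_squared": round(self.amplification.r_squared, 4),
            "amplification_accepted": self.amplification.accepted,
            "i50f_rstar": round(self.hill.half_saturation, 3),
            "i50f_r_squared": round(self.hill.r_squared, 4),
            "i50cs_rstar_s": round(self.i50cs.half_saturation, 2),
            "i50cs_r_squared": round(self.i50cs.r_squared, 4),
            "h0": {
                f: {
                    "h0": round(r.h0, 4),
                    "r_squared": round(r.r_squared, 4) if np.isfinite(r.r_squared) else None,
                    "rmse": round(r.rmse, 4),
                    "converged": r.converged,
                }
                for f, r in self.h0_by_frequency.items()
            },
        }


@dataclass(frozen=True)
class ComparisonReport:
    """Two genotype analyses plus the sensitivity-shift decomposition."""

    control: GenotypeAnalysis
    test: GenotypeAnalysis
    decomposition: SensitivityDecomposition
    config: dict[str, Any] = field(repr=False, default_factory=dict)

    def summary(self) -> dict[str, Any]:
        d = self.decomposition
        return {
            "control": self.control.summary(),
            "test": self.test.summary(),
            "decomposition": {
                "fold_kinetics": round(d.fold_kinetics, 4),
                "fold_kinetics_2dp": round(d.fold_kinetics, 2),
                "fold_collecting_area": round(d.fold_collecting_area, 4),
                "fold_collecting_area_2dp": round(d.fold_collecting_area, 2),
                "fold_amplification": round(d.fold_amplification, 4),
                "fold_total_predicted": round(d.fold_total_predicted, 4),
                "fold_measured": None if d.fold_measured is None else round(d.fold_measured, 4),
            },
        }


def _resolve_config(config: dict[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping or a YAML file of one")
    resolved = dict(_DEFAULTS)
    resolved.update(config)
    for key in ("control", "test"):
        if key not in resolved:
            raise ConfigurationError(f"config must name a {key!r} genotype preset")
    return resolved


def _noise(cfg: dict[str, Any], offset: int) -> NoiseSpec:
    sd = float(cfg["noise_sd"])
    seed = (int(cfg["seed"]) + offset) % 2**31 if sd > 0 else None
    return NoiseSpec(sd=sd, seed=seed)


def _magnitude_data(
    preset: GenotypePreset, cfg: dict[str, Any], frequency: float, offset: int
) -> MagnitudeFunction:
    lo, hi = cfg["irradiance_range"]
    irr = np.logspace(np.log10(lo), np.log10(hi), int(cfg["n_irradiances"]))
    mags = np.array([
        flicker_magnitude(preset.rod, StimulusSpec(i, cfg["contrast"], frequency))
        for i in irr
    ])
    mags = _noise(cfg, offset).average_trials(mags, _noise(cfg, offset).rng())
    return MagnitudeFunction(irr, np.clip(mags, 0.0, None), frequency,
                             cfg["contrast"], preset.name)


def _analyze_genotype(
    preset: GenotypePreset, cfg: dict[str, Any], seed_offset: int,
    files: dict[str, Any] | None = None,
) -> GenotypeAnalysis:
    files = files or {}
    log.info("[%s] generating/loading flash families", preset.name)
    if "flash_family_sat" in files:
        fam_sat: FlashFamily = rio.read_flash_family(files["flash_family_sat"])
    else:
        fam_sat = make_flash_family(
            preset, np.asarray(cfg["flash_strengths_sat"], dtype=float),
            _noise(cfg, seed_offset + 1),
        )
    if "flash_family_dim" in files:
        fam_dim: FlashFamily = rio.read_flash_family(files["flash_family_dim"])
    else:
        fam_dim = make_flash_family(
            preset, np.asarray(cfg["flash_strengths_dim"], dtype=float),
            _noise(cfg, seed_offset + 2),
        )

    log.info("[%s] Pepperberg regression (tau_D)", preset.name)
    tau_fit = pepperberg_tau(fam_sat)
    log.info("[%s] tau_D = %.1f ms (R^2 = %.4f)", preset.name,
             tau_fit.tau_d_s * 1e3, tau_fit.r_squared)

    log.info("[%s] amplification fit", preset.name)
    amp_fit = fit_amplification(fam_dim)
    log.info("[%s] amplification = %.2f s^-2 (R^2 = %.4f)", preset.name,
             amp_fit.amplification_s2, amp_fit.r_squared)

    log.info("[%s] Hill fit of flash intensity-response", preset.name)
    by_strength = {
        float(phi): tr
        for fam in (fam_dim, fam_sat)
        for phi, tr in zip(fam.flash_strengths, fam.traces)
    }
    strengths = np.array(sorted(by_strength))
    peaks = np.array([by_strength[phi].voltage_uv.max() for phi in strengths])
    hill = hill_fit(strengths, np.clip(peaks, 0.0, 1.0))

    log.info("[%s] circulating-current suppression fit (I_50CS)", preset.name)
    if "suppression_curve" in files:
        curve: SuppressionCurve = rio.read_suppression_curve(files["suppression_curve"])
    else:
        curve = make_suppression_curve(
            preset, np.asarray(cfg["backgrounds"], dtype=float),
            _noise(cfg, seed_offset + 3),
        )
    i_circ = circ_suppression(curve)
    i50cs = fit_i50cs(curve.backgrounds[1:], i_circ[1:])

    h0_fits: dict[float, FitResult] = {}
    for k, f in enumerate(cfg["frequencies_hz"]):
        log.info("[%s] h0 fit at %g Hz", preset.name, f)
        if "magnitude_functions" in files and str(f) in files["magnitude_functions"]:
            data = rio.read_magnitude_function(files["magnitude_functions"][str(f)])
        else:
            data = _magnitude_data(preset, cfg, float(f), seed_offset + 4 + k)
        h0_fits[float(f)] = fit_h0(data, preset.rod)

    return GenotypeAnalysis(preset, tau_fit, amp_fit, hill, i50cs, h0_fits)


def run_compare(
    config: dict[str, Any] | str | Path, out_dir: str | Path | None = None
) -> ComparisonReport:
    """Run the full control-versus-test comparison described in the module
    docstring and (optionally) write report, tables and resolved config."""
    cfg = _resolve_config(config)
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)

    control = _analyze_genotype(get_preset(cfg["control"]), cfg, 0,
                                cfg.get("control_files"))
    test = _analyze_genotype(get_preset(cfg["test"]), cfg, 100,
                             cfg.get("test_files"))

    measured = None
    if control.i50cs.well_conditioned and test.i50cs.well_conditioned:
        measured = test.i50cs.half_saturation / control.i50cs.half_saturation
    decomp = sensitivity_shift(control.preset.rod, test.preset.rod, measured)

    report = ComparisonReport(control, test, decomp, cfg)
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: ComparisonReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = {k: v for k, v in report.config.items()}
    rio.write_manifest(cfg, out_dir / "resolved_config.yaml")
    rio.write_manifest(report.summary(), out_dir / "report.yaml")
    for which, analysis in (("control", report.control), ("test", report.test)):
        rows = []
        for f, r in analysis.h0_by_frequency.items():
            rows.append({"frequency_hz": f, "h0": r.h0, "r_squared": r.r_squared,
                         "rmse": r.rmse, "converged": r.converged})
        import pandas as pd

        pd.DataFrame(rows).to_csv(out_dir / f"{which}_h0_fits.csv", index=False)
    log.info("report written to %s", out_dir)


# ---------------------------------------------------------------------------
# single-stage dispatch (used by the CLI)

def _stage_f0(inputs: dict[str, Any]) -> dict[str, Any]:
    from .features import fundamental_magnitude

    trace = rio.read_trace(inputs["trace"])
    f0 = float(inputs.get("frequency_hz")
               or trace.stimulus.frequency_hz)  # type: ignore[union-attr]
    return {"frequency_hz": f0, "f0_uv": fundamental_magnitude(trace, f0)}


def _stage_tcs(inputs: dict[str, Any]) -> dict[str, Any]:
    from .features import contrast_threshold

    series = rio.read_contrast_series(inputs["contrast_series"])
    res = contrast_threshold(series, float(inputs.get("criterion_uv", 10.0)))
    return {
        "attained": res.attained, "threshold_contrast": res.threshold_contrast,
        "tcs": res.tcs, "slope": res.slope, "reason": res.reason,
    }


def _stage_tcsf(inputs: dict[str, Any]) -> dict[str, Any]:
    from .features import build_tcsf

    series = [rio.read_contrast_series(p) for p in inputs["contrast_series"]]
    tcsf = build_tcsf(series, float(inputs.get("criterion_uv", 10.0)))
    return {
        "frequencies_hz": tcsf.frequencies_hz.tolist(),
        "sensitivities": [None if np.isnan(s) else float(s)
                          for s in tcsf.sensitivities],
    }


def _stage_tau_d(inputs: dict[str, Any]) -> dict[str, Any]:
    if "saturation_table" in inputs:
        from .features import pepperberg_regression

        phi, tsat = rio.read_saturation_table(inputs["saturation_table"])
        fit = pepperberg_regression(phi, tsat)
    else:
        fam = rio.read_flash_family(inputs["flash_family"])
        fit = pepperberg_tau(fam, float(inputs.get("recovery_level", 0.6)))
    return {"tau_d_ms": fit.tau_d_s * 1e3, "intercept_s": fit.intercept_s,
            "r_squared": fit.r_squared, "n_used": fit.n_used}


def _stage_amplification(inputs: dict[str, Any]) -> dict[str, Any]:
    fam = rio.read_flash_family(inputs["flash_family"])
    fit = fit_amplification(
        fam,
        t_window_s=float(inputs.get("t_window_s", 0.075)),
        amp_cutoff=float(inputs.get("amp_cutoff", 0.2)),
        max_strength=float(inputs.get("max_strength", 100.0)),
        model=inputs.get("model", "saturating"),
        area_ratio=float(inputs.get("area_ratio", 1.0)),
    )
    return {"amplification_s2": fit.amplification_s2, "t_eff_s": fit.t_eff_s,
            "r_squared": fit.r_squared, "accepted": fit.accepted}


def _stage_hill(inputs: dict[str, Any]) -> dict[str, Any]:
    fam = rio.read_flash_family(inputs["flash_family"])
    peaks = np.array([tr.voltage_uv.max() for tr in fam.traces])
    fit = hill_fit(fam.flash_strengths, np.clip(peaks, 0.0, 1.0))
    return {"i50f_rstar": fit.half_saturation, "r_squared": fit.r_squared,
            "well_conditioned": fit.well_conditioned}


def _stage_i50cs(inputs: dict[str, Any]) -> dict[str, Any]:
    curve = rio.read_suppression_curve(inputs["suppression_curve"])
    i_circ = circ_suppression(curve)
    exclude = inputs.get("exclude_backgrounds_above")
    fit = fit_i50cs(curve.backgrounds[1:], i_circ[1:],
                    None if exclude is None else float(exclude))
    return {"i50cs_rstar_s": fit.half_saturation, "r_squared": fit.r_squared,
            "well_conditioned": fit.well_conditioned}


def _stage_fit_h0(inputs: dict[str, Any]) -> dict[str, Any]:
    data = rio.read_magnitude_function(inputs["magnitude_function"])
    preset = get_preset(inputs["preset"])
    fit = fit_h0(data, preset.rod)
    return {"h0": fit.h0, "r_squared": fit.r_squared, "rmse": fit.rmse,
            "converged": fit.converged}


def _stage_simulate(inputs: dict[str, Any]) -> dict[str, Any]:
    preset = get_preset(inputs["preset"])
    out_dir = Path(inputs.get("out", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(inputs.get("seed", 0))
    sd = float(inputs.get("noise_sd", 0.0))  # suppression amplitudes, uV
    flash_sd = float(inputs.get("flash_noise_sd", 0.0))  # normalized units
    fam = make_flash_family(
        preset, np.asarray(inputs.get("flash_strengths",
                                      _DEFAULTS["flash_strengths_sat"]), dtype=float),
        NoiseSpec(sd=flash_sd, seed=seed if flash_sd > 0 else None),
    )
    rio.write_flash_family(fam, out_dir / "flash_family.csv")
    curve = make_suppression_curve(
        preset, np.asarray(inputs.get("backgrounds", _DEFAULTS["backgrounds"]),
                           dtype=float),
        NoiseSpec(sd=sd, seed=seed + 1 if sd > 0 else None))
    rio.write_suppression_curve(curve, out_dir / "suppression_curve.csv")
    manifest = {"preset": preset.name, "seed": seed, "noise_sd": sd,
                "flash_noise_sd": flash_sd,
                "files": ["flash_family.csv", "suppression_curve.csv"]}
    rio.write_manifest(manifest, out_dir / "manifest.yaml")
    return {"out_dir": str(out_dir), **manifest}


STAGES = {
    "f0": _stage_f0,
    "tcs": _stage_tcs,
    "tcsf": _stage_tcsf,
    "tau_d": _stage_tau_d,
    "amplification": _stage_amplification,
    "hill": _stage_hill,
    "i50cs": _stage_i50cs,
    "fit_h0": _stage_fit_h0,
    "simulate": _stage_simulate,
}


def run_stage(stage: str, inputs: dict[str, Any]) -> dict[str, Any]:
    """Run exactly one named analysis stage on file inputs; see ``STAGES``."""
    try:
        func = STAGES[stage]
    except KeyError:
        raise ConfigurationError(
            f"unknown stage {stage!r}; known: {sorted(STAGES)}"
        ) from None
    return func(inputs)
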