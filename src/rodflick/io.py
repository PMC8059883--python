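"""Delimited-text I/O for traces, summary series and datasets.

All numeric files are comma-separated UTF-8 with a header row and '.'
decimals.  File-level metadata (stimulus frequency, mean irradiance, flash
strength, preset, seed) travels in ``# key: value`` comment lines at the top
of each file, or in a dataset-wide ``manifest.yaml``.

Column conventions:

* traces:            ``time_s, voltage_uv``
* contrast series:   ``contrast, f0_uv``
* saturation table:  ``flash_rstar, tsat_s``
* flash family:      ``flash_rstar, time_s, response`` (long format)
* suppression curve: ``background_rstar_s, awave_uv``
* magnitude function:``irradiance_rstar_s, f0_uv``
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .features import ContrastSeries, FlashFamily, SuppressionCurve, Trace
from .fitting import MagnitudeFunction
from .model import StimulusSpec

__all__ = [
    "read_trace", "write_trace",
    "read_contrast_series", "write_contrast_series",
    "read_flash_family", "write_flash_family",
    "read_saturation_table", "write_saturation_table",
    "read_suppression_curve", "write_suppression_curve",
    "read_magnitude_function", "write_magnitude_function",
    "write_manifest", "read_manifest",
]


def _write_csv(path: Path, df: pd.DataFrame, meta: dict[str, Any]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            if value is not None:
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> tuple[pd.DataFrame, dict[str, str]]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    return df, meta


def _require(df: pd.DataFrame, cols: tuple[str, ...], path: Path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")


def write_trace(trace: Trace, path: str | Path) -> None:
    meta: dict[str, Any] = {}
    if isinstance(trace.stimulus, StimulusSpec):
        meta = {
            "mean_irradiance": trace.stimulus.mean_irradiance,
            "contrast": trace.stimulus.contrast,
            "frequency_hz": trace.stimulus.frequency_hz,
        }
    elif trace.stimulus is not None:
        meta = {"flash_rstar": float(trace.stimulus)}
    df = pd.DataFrame({"time_s": trace.time_s, "voltage_uv": trace.voltage_uv})
    _write_csv(Path(path), df, meta)


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df, meta = _read_csv(path)
    _require(df, ("time_s", "voltage_uv"), path)
    stimulus: StimulusSpec | float | None = None
    if "frequency_hz" in meta:
        stimulus = StimulusSpec(
            float(meta.get("mean_irradiance", 0.0)),
            float(meta.get("contrast", 0.0)),
            float(meta["frequency_hz"]),
        )
    elif "flash_rstar" in meta:
        stimulus = float(meta["flash_rstar"])
    return Trace(df["time_s"].to_numpy(), df["voltage_uv"].to_numpy(), stimulus)


def write_contrast_series(series: ContrastSeries, path: str | Path) -> None:
    df = pd.DataFrame({"contrast": series.contrasts, "f0_uv": series.magnitudes_uv})
    _write_csv(Path(path), df, {
        "frequency_hz": series.frequency_hz,
        "mean_irradiance": series.mean_irradiance,
    })


def read_contrast_series(path: str | Path) -> ContrastSeries:
    path = Path(path)
    df, meta = _read_csv(path)
    _require(df, ("contrast", "f0_uv"), path)
    if "frequency_hz" not in meta:
        raise InputError(f"{path}: missing '# frequency_hz:' metadata line")
    return ContrastSeries(
        df["contrast"].to_numpy(), df["f0_uv"].to_numpy(),
        float(meta["frequency_hz"]), float(meta.get("mean_irradiance", 0.0)),
    )


def write_flash_family(family: FlashFamily, path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "flash_rstar": phi, "time_s": tr.time_s, "response": tr.voltage_uv,
        })
        for phi, tr in zip(family.flash_strengths, family.traces)
    ]
    _write_csv(Path(path), pd.concat(frames, ignore_index=True), {})


def read_flash_family(path: str | Path) -> FlashFamily:
    path = Path(path)
    df, _ = _read_csv(path)
    _require(df, ("flash_rstar", "time_s", "response"), path)
    strengths = np.sort(df["flash_rstar"].unique())
    traces = []
    for phi in strengths:
        sub = df[df["flash_rstar"] == phi]
        traces.append(Trace(sub["time_s"].to_numpy(), sub["response"].to_numpy(),
                            float(phi)))
    return FlashFamily(strengths, tuple(traces))


def write_saturation_table(
    flash_strengths: np.ndarray, tsat_s: np.ndarray, path: str | Path
) -> None:
    df = pd.DataFrame({"flash_rstar": flash_strengths, "tsat_s": tsat_s})
    _write_csv(Path(path), df, {})


def read_saturation_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    df, _ = _read_csv(path)
    _require(df, ("flash_rstar", "tsat_s"), path)
    return df["flash_rstar"].to_numpy(), df["tsat_s"].to_numpy()


def write_suppression_curve(curve: SuppressionCurve, path: str | Path) -> None:
    df = pd.DataFrame({
        "background_rstar_s": curve.backgrounds,
        "awave_uv": curve.awave_amplitudes_uv,
    })
    _write_csv(Path(path), df, {})


def read_suppression_curve(path: str | Path) -> SuppressionCurve:
    path = Path(path)
    df, _ = _read_csv(path)
    _require(df, ("background_rstar_s", "awave_uv"), path)
    return SuppressionCurve(df["background_rstar_s"].to_numpy(),
                            df["awave_uv"].to_numpy())


def write_magnitude_function(data: MagnitudeFunction, path: str | Path) -> None:
    df = pd.DataFrame({
        "irradiance_rstar_s": data.irradiances, "f0_uv": data.magnitudes_uv,
    })
    _write_csv(Path(path), df, {
        "frequency_hz": data.frequency_hz,
        "contrast": data.contrast,
        "genotype_label": data.genotype_label or None,
    })


def read_magnitude_function(path: str | Path) -> MagnitudeFunction:
    path = Path(path)
    df, meta = _read_csv(path)
    _require(df, ("irradiance_rstar_s", "f0_uv"), path)
    for key in ("frequency_hz", "contrast"):
        if key not in meta:
            raise InputError(f"{path}: missing '# {key}:' metadata line")
    return MagnitudeFunction(
        df["irradiance_rstar_s"].to_numpy(), df["f0_uv"].to_numpy(),
        float(meta["frequency_hz"]), float(meta["contrast"]),
        meta.get("genotype_label", ""),
    )


def _to_builtin(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays so yaml.safe_dump accepts them."""
    if isinstance(obj, dict):
        return {_to_builtin(k): _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_builtin(v) for v in obj.tolist()]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_manifest(manifest: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_builtin(manifest), sort_keys=True))


def read_manifest(path: str | Path) -> dict[str, Any]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise InputError(f"{path}: manifest must be a mapping")
    return data
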