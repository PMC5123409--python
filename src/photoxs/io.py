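"""Readers and writers for spectra, light sources, protocols and results.

All tabular data travels as plain CSV so that files diff cleanly and round
trips are lossless (floats are written with shortest-repr precision, which
Python parses back bit-exactly; the saturation time point is written as
``inf``).  Protocols and results are JSON (YAML accepted for protocol
configs), each carrying a ``schema`` field for versioning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import (
    DARK,
    LightPhase,
    LightProtocol,
    LightSource,
    ReversionModel,
    ReversionPool,
)
from .reversion import ReversionFit
from .spectra import SpectraSeries

__all__ = [
    "read_light_source",
    "write_light_source",
    "read_spectra",
    "write_spectra",
    "read_protocol",
    "write_reversion",
    "read_reversion",
    "write_fit_result",
    "RunConfig",
    "IOError_",
]

SCHEMA_SPECTRA = "photoxs/spectra-v1"
SCHEMA_REVERSION = "photoxs/reversion-v1"
SCHEMA_FIT = "photoxs/fit-v1"


class IOError_(ValueError):
    """Malformed input file."""


def _fmt(x: float) -> str:
    # shortest repr that round-trips the float64 bit pattern exactly
    return repr(float(x))


def write_light_source(source: LightSource, path: str | Path) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": source.wavelengths, "fluence_umol_m2_s": source.fluence}
    )
    df.to_csv(path, index=False, float_format=_fmt)


def read_light_source(path: str | Path, label: str | None = None) -> LightSource:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"wavelength_nm", "fluence_umol_m2_s"}
    if not required.issubset(df.columns):
        raise IOError_(f"{path}: light-source CSV needs columns {sorted(required)}")
    return LightSource(
        df["wavelength_nm"].to_numpy(float),
        df["fluence_umol_m2_s"].to_numpy(float),
        label=label or Path(path).stem,
    )


def write_spectra(series: SpectraSeries, path: str | Path) -> None:
    """Long-format CSV: wavelength_nm, time_s, absorbance[, error]."""
    rows = {
        "wavelength_nm": np.tile(series.wavelengths, series.times.size),
        "time_s": np.repeat(series.times, series.wavelengths.size),
        "absorbance": series.absorbance.ravel(),
    }
    if series.errors is not None:
        rows["error"] = series.errors.ravel()
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_fmt)


def read_spectra(path: str | Path, label: str = "") -> SpectraSeries:
    """Read a long-format spectra CSV into a validated series.

    A missing ``error`` column means nu = 1 everywhere (``errors=None``).
    Deferred validation: a series without a t = 0 block loads fine; forming
    difference spectra from it errors later.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"wavelength_nm", "time_s", "absorbance"}
    if not required.issubset(df.columns):
        raise IOError_(f"{path}: spectra CSV needs columns {sorted(required)}")
    if df[list(required)].isna().any().any():
        raise IOError_(f"{path}: spectra CSV contains missing values")
    if df.duplicated(["wavelength_nm", "time_s"]).any():
        raise IOError_(f"{path}: duplicate (wavelength, time) pairs")
    times = np.sort(df["time_s"].unique())
    wl = np.sort(df["wavelength_nm"].unique())
    pivot = df.pivot(index="time_s", columns="wavelength_nm", values="absorbance")
    pivot = pivot.sort_index().sort_index(axis=1)
    if pivot.isna().any().any():
        raise IOError_(f"{path}: the (wavelength x time) table is not complete")
    errors = None
    if "error" in df.columns:
        err = df.pivot(index="time_s", columns="wavelength_nm", values="error")
        errors = err.sort_index().sort_index(axis=1).to_numpy(float)
    return SpectraSeries(
        wavelengths=wl,
        times=times,
        absorbance=pivot.to_numpy(float),
        errors=errors,
        label=label or Path(path).stem,
    )


def _phase_from_config(entry: dict, base_dir: Path) -> LightPhase:
    duration = entry.get("duration_s", "saturate")
    duration = math.inf if duration == "saturate" else float(duration)
    source = entry.get("source", "dark")
    if source == "dark":
        return LightPhase(duration, DARK)
    if isinstance(source, dict) and "gaussian" in source:
        from .synthgen import gaussian_led

        g = source["gaussian"]
        return LightPhase(
            duration,
            gaussian_led(float(g["center_nm"]), float(g["fwhm_nm"]), float(g["total_fluence"])),
        )
    if isinstance(source, str):
        return LightPhase(duration, read_light_source(base_dir / source))
    raise IOError_(f"unrecognised light-source entry: {source!r}")


def read_protocol(path: str | Path) -> LightProtocol:
    """Protocol config: a JSON/YAML list of phases.

    Each phase is ``{"duration_s": seconds | "saturate",
    "source": "dark" | <light CSV path> | {"gaussian": {center_nm, fwhm_nm,
    total_fluence}}}``.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    if not isinstance(data, list) or not data:
        raise IOError_(f"{path}: protocol config must be a non-empty list of phases")
    return LightProtocol(tuple(_phase_from_config(p, path.parent) for p in data))


def write_reversion(fit: ReversionFit, path: str | Path) -> None:
    payload = {
        "schema": SCHEMA_REVERSION,
        "pools": [
            {
                "alpha": p.alpha,
                "alpha_ci95": list(fit.ci95.get("alpha_1", (math.nan, math.nan)))
                if i == 0
                else None,
                "beta": p.beta,
                "ci95": list(fit.ci95.get(f"beta_{i + 1}", (math.nan, math.nan))),
            }
            for i, p in enumerate(fit.model.pools)
        ],
        "chi2": fit.chi2,
        "aicc": fit.aicc,
        "n_pools": fit.n_pools,
        "at_boundary": fit.at_boundary,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_reversion(path: str | Path) -> ReversionModel:
    payload = json.loads(Path(path).read_text())
    return ReversionModel(
        tuple(ReversionPool(p["alpha"], p["beta"]) for p in payload["pools"])
    )


def write_fit_result(result, path: str | Path) -> None:
    """fit.json with scalar results; spectra written as a CSV next to it."""
    path = Path(path)
    payload = {
        "schema": SCHEMA_FIT,
        "phi_A": result.phi_A,
        "phi_I": result.phi_I,
        "R": result.R,
        "chi2": result.chi2,
        "X1": result.X[0],
        "X2": result.X[1],
        "R_max": result.space.R_max,
        "seed": result.seed,
        "n_starts": len(result.starts),
        "ci95": {k: list(v) for k, v in result.ci95.items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    pd.DataFrame(
        {
            "wavelength_nm": result.wavelengths,
            "epsilon_I": result.epsilon_I,
            "epsilon_A": result.epsilon_A,
            "sigma_I": result.sigma_I,
            "sigma_A": result.sigma_A,
        }
    ).to_csv(path.with_suffix(".spectra.csv"), index=False)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    File paths are resolved relative to the config's own directory when loaded
    from disk.  ``n_pools = 0`` declares a reversion-free receptor (no dark
    dynamics expected).
    """

    forward: str
    reverse: str
    dark: str | None = None
    c_tot: float = 0.34 / 70000.0
    path_length: float = 1.06
    light_act: str | dict | None = None
    light_inact: str | dict | None = None
    n_pools: int = 1
    n_phi: int = 50
    phi_min: float = 1e-3
    n_starts: int = 100
    seed: int = 0
    base_dir: Path = dc_field(default_factory=Path)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        cfg = cls(**data)
        cfg.base_dir = path.parent
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.c_tot <= 0 or self.path_length <= 0:
            raise IOError_("sample constants must be positive")
        for name in ("forward", "reverse", "dark"):
            p = getattr(self, name)
            if p is not None and not (self.base_dir / p).exists():
                raise IOError_(f"{name} spectra file not found: {p}")

    def _light(self, entry) -> LightSource:
        if isinstance(entry, dict) and "gaussian" in entry:
            from .synthgen import gaussian_led

            g = entry["gaussian"]
            return gaussian_led(
                float(g["center_nm"]), float(g["fwhm_nm"]), float(g["total_fluence"])
            )
        if isinstance(entry, str):
            return read_light_source(self.base_dir / entry)
        raise IOError_(f"unrecognised light-source entry: {entry!r}")

    @property
    def lights(self) -> tuple[LightSource, LightSource]:
        return self._light(self.light_act), self._light(self.light_inact)
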