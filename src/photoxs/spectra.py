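"""Absorbance spectra from state fractions, and difference spectra.

The Beer-Lambert convention used throughout is

    A(lambda, t) = 2.303 * l * c_tot * sum_k c^k(t) * eps_k^lambda,

with ``eps_k = sigma_k / Phi_k`` (m^2 mol^-1), ``l`` in cm, ``c_tot`` in
mol L^-1 and the state fractions ``c^k`` summing to the number of chromophores
per molecule ``n_c``.  The scaled spectra ``eps_hat = 2.303 l c_tot eps`` are
only ever formed as views, never stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .kinetics import (
    KineticsError,
    LightProtocol,
    PhotoreceptorModel,
    StateFractions,
    dark_adapted_state,
    propagate,
)

__all__ = [
    "BEER_LAMBERT",
    "beer_lambert_scale",
    "AbsorbanceSpectrum",
    "SpectraSeries",
    "simulate_absorbance",
    "difference_series",
    "SpectraError",
]

BEER_LAMBERT = 2.303


class SpectraError(ValueError):
    pass


def beer_lambert_scale(c_tot: float, path_length: float) -> float:
    """The factor 2.303 * l * c_tot mapping eps (m^2 mol^-1) to absorbance."""
    return BEER_LAMBERT * path_length * c_tot


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """A single absorbance spectrum at one time point of a protocol."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.shape != ab.shape:
            raise SpectraError("absorbance does not match the wavelength grid")
        if not np.all(np.isfinite(ab)):
            raise SpectraError("absorbance must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class SpectraSeries:
    """Absorbance A(lambda, t) measured (or simulated) under one protocol.

    ``times`` are seconds since the start of the experimental phase and may
    end with ``inf`` for the saturation (plateau) spectrum.  ``errors`` holds
    the per-point measurement error nu (same shape as ``absorbance``); ``None``
    means nu = 1, the convention for noiseless synthetic data.
    """

    wavelengths: np.ndarray
    times: np.ndarray
    absorbance: np.ndarray  # shape (n_times, n_wavelengths)
    errors: np.ndarray | None = None
    prep: LightProtocol | None = None
    exp: LightProtocol | None = None
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise SpectraError("times must be 1-D and strictly increasing")
        if a.shape != (t.size, wl.size):
            raise SpectraError(
                f"absorbance shape {a.shape} does not match (n_times={t.size}, n_wl={wl.size})"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)
        if self.errors is not None:
            err = np.asarray(self.errors, dtype=float)
            if err.shape != a.shape:
                raise SpectraError("errors must match the absorbance shape")
            if np.any(err < 0):
                raise SpectraError("errors must be non-negative")
            object.__setattr__(self, "errors", err)

    @property
    def has_time_zero(self) -> bool:
        return bool(np.any(self.times == 0.0))

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.times)

    def at_time(self, t: float) -> np.ndarray:
        idx = np.nonzero(self.times == t)[0]
        if idx.size == 0:
            raise SpectraError(f"no spectrum at t = {t}")
        return self.absorbance[idx[0]]

    @property
    def saturation(self) -> np.ndarray:
        """The t -> inf (plateau) spectrum."""
        return self.at_time(math.inf)

    def with_absorbance(self, absorbance: np.ndarray, errors=None) -> "SpectraSeries":
        return replace(self, absorbance=absorbance, errors=errors)


def simulate_absorbance(
    model: PhotoreceptorModel,
    prep: LightProtocol,
    exp: LightProtocol,
    times: Sequence[float],
    c0: StateFractions | None = None,
    label: str = "",
) -> SpectraSeries:
    """Simulate A(lambda, t) for a preparatory then experimental protocol.

    The population starts dark-adapted (unless ``c0`` is given), is propagated
    through ``prep``, and sampled during ``exp`` at the requested ``times``
    (seconds from the start of the experimental phase; ``inf`` is allowed and
    yields the saturation spectrum).
    """
    t = np.asarray(times, dtype=float)
    order = np.argsort(t)
    t_sorted = t[order]
    start = propagate(model, prep, c0)
    finite = np.isfinite(t_sorted)
    states: list[StateFractions] = [None] * t_sorted.size  # type: ignore[list-item]
    fin_states = propagate(model, exp, start, t_sorted[finite])
    it = iter(fin_states)
    for i, isfin in enumerate(finite):
        states[i] = next(it) if isfin else None
    if np.any(~finite):
        sat = propagate(model, exp, start)  # full protocol incl. inf phases
        for i, isfin in enumerate(finite):
            if not isfin:
                states[i] = sat

    eps_I, eps_A = model.epsilon_I, model.epsilon_A
    scale = beer_lambert_scale(model.c_tot, model.path_length)
    spectra = np.empty((t_sorted.size, model.wavelengths.size))
    for i, st in enumerate(states):
        spectra[i] = scale * (st.c_A * eps_A + st.c_I * eps_I)
    return SpectraSeries(
        wavelengths=model.wavelengths,
        times=t_sorted,
        absorbance=spectra,
        prep=prep,
        exp=exp,
        label=label,
    )


def difference_series(series: SpectraSeries) -> np.ndarray:
    """Difference spectra D(t, lambda) = A(lambda, t) - A(lambda, 0).

    One row per time point of the series (the t = 0 row is identically zero).
    """
    if not series.has_time_zero:
        raise SpectraError("difference spectra require a t = 0 spectrum")
    a0 = series.at_time(0.0)
    return series.absorbance - a0[None, :]
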