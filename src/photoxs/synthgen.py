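"""Synthetic photoreceptor datasets: LED sources, presets, noise.

Every input the estimation pipeline needs can be generated here, so the whole
method is testable without laboratory spectra.  The presets emulate the
standard bench configuration for this kind of experiment: Gaussian LED
illumination at 11 umol m^-2 s^-1, Gaussian cross-section bands (peak
amplitudes 1e4 m^2 mol^-1 for the cyanobacteriochrome-like presets — switching
within minutes — and 3e5 m^2 mol^-1 for the plant-phytochrome-like red/far-red
presets — switching within seconds, fast against thermal reversion), a
0.34 mg/ml sample of a 70 kDa protein in a path-corrected 1.06 cm cuvette,
five measurement time points per illumination series, and multiplicative
noise with a 10 % coefficient of variation where noise is modelled at all.

Presets
-------
``redgreen``
    Red/green cyanobacteriochrome: non-overlapping bands (activation 660 nm,
    inactivation 550 nm), no thermal reversion, Phi_A = 0.1, Phi_I = 0.34.
    Both saturating lights reach pure populations, so the classical
    two-condition (Butler) analysis is exact here.
``overlap680``
    Activation 660 nm, inactivation 680 nm with heavily overlapping bands,
    Phi_A = 0.1, Phi_I = 0.3; neither light reaches a pure population, which
    is precisely where the Butler analysis breaks down.
``dual_reversion``
    Red/far-red receptor (660/730 nm bands overlapping in the red) whose
    active population splits 70/30 into pools reverting at 0.005 and
    0.0005 s^-1.
``dimer``
    Same bands, dimeric receptor whose AA homo-dimer and AI hetero-dimer
    revert at per-protomer rates an order of magnitude apart.
``noisy_rf``
    Red/far-red receptor with a single reversion rate of 0.005 s^-1,
    Phi_A = 0.1, Phi_I = 0.2, and 10 % multiplicative measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinetics import (
    CrossSectionSet,
    DARK,
    KineticsError,
    LightProtocol,
    LightSource,
    PhotoreceptorModel,
    QuantumYields,
    ReversionModel,
    ReversionPool,
    Structure,
)
from .spectra import SpectraSeries, simulate_absorbance  # noqa: F401  (SpectraSeries in signatures)

__all__ = [
    "DEFAULT_GRID",
    "PRESET_NAMES",
    "TestCasePreset",
    "gaussian_led",
    "gaussian_band",
    "make_preset",
    "generate_dataset",
    "add_noise",
]

#: 1-nm wavelength grid used by all presets (nm).
DEFAULT_GRID = np.arange(400.0, 801.0, 1.0)

_FWHM_TO_SD = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def gaussian_led(
    center: float,
    fwhm: float,
    total_fluence: float,
    grid: np.ndarray | None = None,
    label: str = "",
) -> LightSource:
    """A Gaussian LED emission profile normalised to a total photon fluence.

    The bin sum of the returned fluence equals ``total_fluence`` exactly.
    """
    if fwhm <= 0:
        raise KineticsError(f"fwhm must be > 0, got {fwhm}")
    if total_fluence < 0:
        raise KineticsError("total fluence must be >= 0")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if not (grid[0] <= center <= grid[-1]):
        raise KineticsError(f"LED centre {center} nm lies outside the grid")
    sd = fwhm * _FWHM_TO_SD
    profile = np.exp(-0.5 * ((grid - center) / sd) ** 2)
    if total_fluence > 0:
        profile = profile * (total_fluence / profile.sum())
    else:
        profile = np.zeros_like(profile)
    return LightSource(grid, profile, label=label or f"LED {center:.0f} nm")


def gaussian_band(
    grid: np.ndarray, center: float, fwhm: float, amplitude: float
) -> np.ndarray:
    """A Gaussian spectral band with the given peak amplitude."""
    sd = fwhm * _FWHM_TO_SD
    return amplitude * np.exp(-0.5 * ((grid - center) / sd) ** 2)


@dataclass(frozen=True)
class TestCasePreset:
    """A fully specified ground-truth system plus its measurement design."""

    name: str
    model: PhotoreceptorModel
    light_act: LightSource
    light_inact: LightSource
    times_light: np.ndarray  # s, the n_t = 5 points of each illumination series
    times_dark: np.ndarray  # s, the n_t = 5 points of the dark-decay series
    noise_cv: float = 0.0

    @property
    def protocol_act(self) -> LightProtocol:
        return LightProtocol.saturating(self.light_act)

    @property
    def protocol_inact(self) -> LightProtocol:
        return LightProtocol.saturating(self.light_inact)

    @property
    def protocol_dark(self) -> LightProtocol:
        return LightProtocol.saturating(DARK)


def _rf_bands(grid: np.ndarray) -> CrossSectionSet:
    """Red/far-red band pair with overlap in the red (plant-phytochrome-like).

    sigma_I peaks at 660 nm; sigma_A peaks at 730 nm with a red shoulder so
    that far-red light cannot fully avoid re-activation and red light drives
    some deactivation.  Amplitudes (peak 3e5 m^2 mol^-1) put light-driven
    switching on the seconds scale at 11 umol m^-2 s^-1 — full-length
    in-vivo-like kinetics, fast against thermal reversion, so the dark-decay
    amplitudes coincide with the pool fractions to high accuracy.
    """
    sigma_I = gaussian_band(grid, 660.0, 70.0, 3.0e5)
    sigma_A = gaussian_band(grid, 730.0, 60.0, 1.8e5) + gaussian_band(
        grid, 670.0, 60.0, 4.5e4
    )
    return CrossSectionSet(grid, sigma_I, sigma_A)


PRESET_NAMES = ("redgreen", "overlap680", "dual_reversion", "dimer", "noisy_rf")


def make_preset(name: str, grid: np.ndarray | None = None) -> TestCasePreset:
    """Build one of the named ground-truth test cases."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    fast_times = np.array([2.0, 5.0, 10.0, 20.0, 45.0])
    rf_times = np.array([0.2, 0.5, 1.2, 3.0, 8.0])
    if name == "redgreen":
        cs = CrossSectionSet(
            grid,
            gaussian_band(grid, 660.0, 50.0, 1.0e4),
            gaussian_band(grid, 550.0, 50.0, 1.1e4),
        )
        return TestCasePreset(
            name,
            PhotoreceptorModel(cs, QuantumYields(0.1, 0.34), ReversionModel.single(0.0)),
            gaussian_led(660.0, 20.0, 11.0, grid),
            gaussian_led(550.0, 20.0, 11.0, grid),
            fast_times,
            np.array([60.0, 240.0, 900.0, 3000.0, 9000.0]),
        )
    if name == "overlap680":
        cs = CrossSectionSet(
            grid,
            gaussian_band(grid, 660.0, 60.0, 1.0e4),
            gaussian_band(grid, 680.0, 60.0, 9.0e3),
        )
        return TestCasePreset(
            name,
            PhotoreceptorModel(cs, QuantumYields(0.1, 0.3), ReversionModel.single(0.0)),
            gaussian_led(660.0, 20.0, 11.0, grid),
            gaussian_led(680.0, 20.0, 11.0, grid),
            fast_times,
            np.array([60.0, 240.0, 900.0, 3000.0, 9000.0]),
        )
    if name == "dual_reversion":
        return TestCasePreset(
            name,
            PhotoreceptorModel(
                _rf_bands(grid),
                QuantumYields(0.1, 0.17),
                ReversionModel((ReversionPool(0.7, 0.005), ReversionPool(0.3, 0.0005))),
            ),
            gaussian_led(660.0, 20.0, 11.0, grid),
            gaussian_led(730.0, 20.0, 11.0, grid),
            rf_times,
            np.array([60.0, 240.0, 900.0, 3000.0, 9000.0]),
        )
    if name == "dimer":
        return TestCasePreset(
            name,
            PhotoreceptorModel(
                _rf_bands(grid),
                QuantumYields(0.1, 0.17),
                ReversionModel((ReversionPool(0.5, 0.005), ReversionPool(0.5, 0.0005))),
                structure=Structure.DIMER,
            ),
            gaussian_led(660.0, 20.0, 11.0, grid),
            gaussian_led(730.0, 20.0, 11.0, grid),
            rf_times,
            np.array([60.0, 240.0, 900.0, 3000.0, 9000.0]),
        )
    if name == "noisy_rf":
        return TestCasePreset(
            name,
            PhotoreceptorModel(
                _rf_bands(grid), QuantumYields(0.1, 0.2), ReversionModel.single(0.005)
            ),
            gaussian_led(660.0, 20.0, 11.0, grid),
            gaussian_led(730.0, 20.0, 11.0, grid),
            rf_times,
            np.array([30.0, 90.0, 250.0, 700.0, 2000.0]),
            noise_cv=0.1,
        )
    raise KineticsError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")


def add_noise(series: SpectraSeries, cv: float, seed: int | None = 0) -> SpectraSeries:
    """Multiplicative Gaussian noise: A -> A (1 + cv xi), xi ~ N(0, 1).

    The per-point error estimate nu is set to cv * |A| of the input series
    (the relative-error model a spectrophotometer user would assume).
    """
    if cv < 0:
        raise KineticsError(f"coefficient of variation must be >= 0, got {cv}")
    if cv == 0:
        return series
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal(series.absorbance.shape)
    noisy = series.absorbance * (1.0 + cv * xi)
    nu = cv * np.abs(series.absorbance)
    return series.with_absorbance(noisy, errors=nu)


def generate_dataset(
    preset: TestCasePreset, seed: int | None = 0
) -> dict[str, SpectraSeries]:
    """Simulate the three series the estimation pipeline consumes.

    ``forward``: saturate with activating light, then watch deactivation under
    inactivating light.  ``reverse``: vice versa.  ``dark``: saturate with
    activating light, then watch thermal reversion in darkness.  Each series
    holds t = 0, the five measurement times and the t -> inf plateau.  If the
    preset carries noise, independent noise realisations (sub-seeded from
    ``seed``) are applied to each series.
    """
    model = preset.model

    def series(prep, exp, times, label):
        t = np.concatenate([[0.0], np.asarray(times, float), [math.inf]])
        return simulate_absorbance(model, prep, exp, t, label=label)

    out = {
        "forward": series(
            preset.protocol_act,
            LightProtocol.constant(preset.light_inact),
            preset.times_light,
            "act->inact",
        ),
        "reverse": series(
            preset.protocol_inact,
            LightProtocol.constant(preset.light_act),
            preset.times_light,
            "inact->act",
        ),
        "dark": series(
            preset.protocol_act,
            LightProtocol.constant(DARK),
            preset.times_dark,
            "act->dark",
        ),
    }
    if preset.noise_cv > 0:
        ss = np.random.SeedSequence(seed).spawn(3)
        out = {
            key: add_noise(s, preset.noise_cv, seed=ss[i])
            for i, (key, s) in enumerate(out.items())
        }
    return out
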