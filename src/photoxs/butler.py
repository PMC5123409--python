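"""Classical two-condition (Butler-style) estimation of sigma and Phi.

The historical analysis of phytochrome spectra assumes that saturating
illuminations drive the population to *known* state fractions — ideally pure
P_A after activating light and pure P_I after inactivating light.  Under that
assumption the two saturated spectra unmix linearly into pure-state extinction
spectra, and the observed mono-exponential approach to photoequilibrium under
each light fixes the quantum yields through the rate balance

    k_obs(light) = Phi_I S_I(light) + Phi_A S_A(light) + beta,

with S_k(light) = sum_lambda eps_k^lambda z^lambda * 1e-6.  The assumed
fractions are explicit inputs here because that assumption is exactly what
fails for photoreceptors whose bands overlap: then no illumination reaches a
pure population, the unmixing is biased, and so are the recovered yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .kinetics import LightSource, photo_rate
from .searchspace import SaturatedPair
from .spectra import SpectraSeries, beer_lambert_scale

__all__ = ["ButlerEstimate", "butler_estimate", "ButlerError"]


class ButlerError(ValueError):
    pass


@dataclass(frozen=True)
class ButlerEstimate:
    wavelengths: np.ndarray
    epsilon_I: np.ndarray
    epsilon_A: np.ndarray
    sigma_I: np.ndarray
    sigma_A: np.ndarray
    phi_A: float
    phi_I: float
    assumed_fractions: tuple[float, float]
    k_obs: tuple[float, float]  # observed rates: (under inactivating, under activating)


def _observed_rate(series: SpectraSeries, n_select: int = 5) -> float:
    """Mono-exponential rate of the approach to photoequilibrium.

    Averages the normalised approach (A(t) - A(inf)) / (A(0) - A(inf)) over
    the ``n_select`` wavelengths of largest spectral change, then fits
    exp(-k t).
    """
    a0 = series.at_time(0.0)
    a_inf = series.saturation
    span = a0 - a_inf
    idx = np.argsort(np.abs(span))[::-1][:n_select]
    if np.allclose(span[idx], 0.0):
        raise ButlerError("series shows no approach to photoequilibrium")
    mask = np.isfinite(series.times) & (series.times > 0)
    t = series.times[mask]
    trace = ((series.absorbance[mask][:, idx] - a_inf[idx]) / span[idx]).mean(axis=1)

    def resid(logk):
        return np.exp(-np.exp(logk[0]) * t) - trace

    # crude log-linear seed from the first usable point
    pos = trace > 1e-12
    k0 = -np.log(trace[pos][0]) / t[pos][0] if np.any(pos) else 1.0 / t[0]
    sol = least_squares(resid, [np.log(max(k0, 1e-12))], method="lm")
    return float(np.exp(sol.x[0]))


def butler_estimate(
    pair: SaturatedPair,
    kinetic_series: tuple[SpectraSeries, SpectraSeries],
    lights: tuple[LightSource, LightSource],
    *,
    c_tot: float,
    path_length: float,
    assumed_fractions: tuple[float, float] = (1.0, 0.0),
    beta: float = 0.0,
) -> ButlerEstimate:
    """Unmix saturated spectra and extract quantum yields, Butler-style.

    ``kinetic_series`` are the (forward, reverse) measurement series — forward
    observed under the inactivating light, reverse under the activating light.
    ``assumed_fractions`` are the active fractions (f_act, f_inact) assumed to
    hold after activating / inactivating saturation.
    """
    f_act, f_inact = assumed_fractions
    for f in (f_act, f_inact):
        if not (0.0 <= f <= 1.0):
            raise ButlerError(f"assumed fractions must lie in [0, 1], got {f}")
    if f_act == f_inact:
        raise ButlerError("equal assumed fractions: unmixing matrix is singular")

    scale = beer_lambert_scale(c_tot, path_length)
    # [A_act; A_inact] = scale * [[f_act, 1-f_act], [f_inact, 1-f_inact]] @ [eps_A; eps_I]
    m = np.array([[f_act, 1.0 - f_act], [f_inact, 1.0 - f_inact]])
    rhs = np.vstack([pair.A_sat_act, pair.A_sat_inact]) / scale
    eps_A, eps_I = np.linalg.solve(m, rhs)

    forward, reverse = kinetic_series
    k_fwd = _observed_rate(forward)  # under inactivating light
    k_rev = _observed_rate(reverse)  # under activating light
    z_act, z_inact = lights
    wl = pair.wavelengths
    s = np.array(
        [
            [photo_rate(wl, eps_I, z_inact), photo_rate(wl, eps_A, z_inact)],
            [photo_rate(wl, eps_I, z_act), photo_rate(wl, eps_A, z_act)],
        ]
    )
    phi_I, phi_A = np.linalg.solve(s, np.array([k_fwd - beta, k_rev - beta]))

    return ButlerEstimate(
        wavelengths=wl,
        epsilon_I=eps_I,
        epsilon_A=eps_A,
        sigma_I=eps_I * phi_I,
        sigma_A=eps_A * phi_A,
        phi_A=float(phi_A),
        phi_I=float(phi_I),
        assumed_fractions=assumed_fractions,
        k_obs=(k_fwd, k_rev),
    )
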