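"""Step 2: the (X1, X2)-parameterised extinction-coefficient family.

Two saturated spectra — after prolonged activating light and after prolonged
inactivating light (or darkness) — span an affine family that must contain the
scaled pure-state extinction spectra:

    eps_hat_I = A_act + X1 (A_inact - A_act),
    eps_hat_A = A_act + X2 (A_inact - A_act),

with scalars X1, X2 fixed by requiring self-consistency: the photostationary
active fractions computed *from* the candidate spectra (via sigma = eps * Phi
and the kinetic steady state, including thermal reversion) must map the
saturated conditions back onto themselves:

    X1 + (X2 - X1) c_act = 0,      X1 + (X2 - X1) c_inact = 1,

where c_act / c_inact are the saturated active fractions under the activating
and inactivating light.  These equations are implicit in (X1, X2) and are
solved by damped fixed-point iteration with a Newton-type root fallback.

Scanning all quantum-yield pairs Phi = (Phi_A, Phi_I) tabulates the search
space used by the optimiser, together with the reversion-free quantum-yield
ratio R^o per cell and its numerical maximum R^max, the upper bound for
R = Phi_A/Phi_I:

    R^o = -(X2/X1) * (S_I / S_A),    R = R^o - (beta/Phi_I) / S_A,

with S_k = sum_lambda eps_k^lambda z_act^lambda * 1e-6.  The subtracted term
is positive whenever beta > 0 (beta, Phi_I and eps_A are positive), so
R <= R^o always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .kinetics import (
    CrossSectionSet,
    LightSource,
    PHOTON_UNIT,
    PhotoreceptorModel,
    QuantumYields,
    ReversionModel,
    Structure,
    photo_rate,
    photo_rates,
    steady_state,
)
from .spectra import SpectraSeries, beer_lambert_scale

__all__ = [
    "SaturatedPair",
    "SearchSpace",
    "SearchSpaceError",
    "solve_X",
    "epsilon_from_X",
    "epsilon_hat_from_X",
    "compute_R",
    "effective_beta",
    "build_search_space",
]


class SearchSpaceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SaturatedPair:
    """Saturated spectra after activating and after inactivating illumination."""

    wavelengths: np.ndarray
    A_sat_act: np.ndarray
    A_sat_inact: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        aa = np.asarray(self.A_sat_act, dtype=float)
        ai = np.asarray(self.A_sat_inact, dtype=float)
        if aa.shape != wl.shape or ai.shape != wl.shape:
            raise SearchSpaceError("saturated spectra must share the wavelength grid")
        if np.allclose(aa, ai):
            raise SearchSpaceError(
                "saturated spectra are identical: no photoswitching information"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "A_sat_act", aa)
        object.__setattr__(self, "A_sat_inact", ai)

    @classmethod
    def from_series(
        cls,
        forward: SpectraSeries,
        reverse: SpectraSeries,
        plateau_rms_warn: float = 0.01,
    ) -> "SaturatedPair":
        """Saturated pair from the two illumination series.

        The forward series (activating prep, inactivating light) plateaus at
        the inactivating-saturated spectrum and vice versa.  If a series has
        no recorded t -> inf spectrum its final time point is used, with a
        plateau check: the last two spectra must differ by < ``plateau_rms_warn``
        RMS relative to the spectral range.
        """

        def plateau(series: SpectraSeries) -> np.ndarray:
            if np.isinf(series.times[-1]):
                return series.absorbance[-1]
            last, prev = series.absorbance[-1], series.absorbance[-2]
            scale = np.abs(series.absorbance).max()
            rms = np.sqrt(np.mean((last - prev) ** 2)) / max(scale, 1e-300)
            if rms > plateau_rms_warn:
                import warnings

                warnings.warn(
                    f"series {series.label!r}: final spectra differ by {rms:.1%} RMS; "
                    "the series may not have reached saturation",
                    stacklevel=2,
                )
            return last

        if not np.array_equal(forward.wavelengths, reverse.wavelengths):
            raise SearchSpaceError("forward and reverse series use different grids")
        return cls(forward.wavelengths, plateau(reverse), plateau(forward))


def epsilon_hat_from_X(x: tuple[float, float], pair: SaturatedPair) -> tuple[np.ndarray, np.ndarray]:
    """The scaled spectra eps_hat_k = A_act + X_k (A_inact - A_act) (monomer view)."""
    x1, x2 = x
    delta = pair.A_sat_inact - pair.A_sat_act
    return pair.A_sat_act + x1 * delta, pair.A_sat_act + x2 * delta


def epsilon_from_X(
    x: tuple[float, float],
    pair: SaturatedPair,
    c_tot: float,
    path_length: float,
    n_c: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Unscaled extinction spectra (eps_I, eps_A) in m^2 mol^-1.

    The affine family A(c) = A_act + (A_inact - A_act)(X1 + (X2 - X1) c)
    evaluates to the all-inactive sample at aggregate active fraction c = 0
    and the all-active sample at c = n_c.  For monomers (n_c = 1) the pure
    spectra sit at affine coordinates X1 and X2 exactly; for dimers the pure
    active spectrum sits at coordinate X1 + (X2 - X1) n_c, and both spectra
    carry the population factor n_c in Beer-Lambert scaling.
    """
    x1, x2 = x
    delta = pair.A_sat_inact - pair.A_sat_act
    scale = beer_lambert_scale(c_tot, path_length) * n_c
    eps_I = (pair.A_sat_act + x1 * delta) / scale
    coord_A = x1 + (x2 - x1) * n_c
    eps_A = (pair.A_sat_act + coord_A * delta) / scale
    return eps_I, eps_A


def _model_from_eps(
    eps_I: np.ndarray,
    eps_A: np.ndarray,
    phi: QuantumYields,
    pair: SaturatedPair,
    reversion: ReversionModel,
    structure: Structure,
    c_tot: float,
    path_length: float,
) -> PhotoreceptorModel:
    # negative lobes of off-optimal candidates are clipped only for rate sums
    cs = CrossSectionSet(
        pair.wavelengths,
        np.clip(eps_I * phi.phi_I, 0.0, None),
        np.clip(eps_A * phi.phi_A, 0.0, None),
    )
    return PhotoreceptorModel(cs, phi, reversion, structure, c_tot, path_length)


def _stationary_fraction(
    k_I: float, k_A: float, reversion: ReversionModel, structure: Structure
) -> float:
    """Aggregate photostationary active fraction c_A for scalar rates >= 0."""
    if structure is Structure.DIMER:
        from .kinetics import _dimer_stationary

        beta_AA = reversion.pools[0].beta
        beta_AI = reversion.pools[-1].beta
        p = _dimer_stationary(k_I, k_A, beta_AA, beta_AI)
        return float(p[1] + 2.0 * p[2])
    alphas, betas = reversion.alphas, reversion.betas
    denoms = k_I + k_A + betas
    if np.any(denoms <= 0):
        raise SearchSpaceError("all rates zero: no photostationary state")
    return float(alphas @ (k_I / denoms))


def _light_basis(
    pair: SaturatedPair, light: LightSource
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(A_act, A_inact - A_act, fluence) interpolated onto the light's grid."""
    wl = pair.wavelengths
    if np.array_equal(wl, light.wavelengths):
        a = pair.A_sat_act
        d = pair.A_sat_inact - pair.A_sat_act
    else:
        a = np.interp(light.wavelengths, wl, pair.A_sat_act, left=0.0, right=0.0)
        inact = np.interp(light.wavelengths, wl, pair.A_sat_inact, left=0.0, right=0.0)
        d = inact - a
    return a, d, light.fluence


def _clipped_rate_sums(
    x1: float, coord_A: float, basis: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> tuple[float, float]:
    """Per-wavelength-clipped photo-rate sums of the candidate spectra.

    Candidate spectra off the optimum can have negative lobes; cross-sections
    are physically non-negative, so each channel is clipped at zero before
    the fluence-weighted sum (this is what lets the iteration traverse
    extrapolated regions of the affine family on its way to the solution).
    """
    a, d, z = basis
    s_I = float(np.clip(a + x1 * d, 0.0, None) @ z) * PHOTON_UNIT
    s_A = float(np.clip(a + coord_A * d, 0.0, None) @ z) * PHOTON_UNIT
    return s_I, s_A


def _fractions_for_X(
    x: np.ndarray,
    phi: QuantumYields,
    pair: SaturatedPair,
    reversion: ReversionModel,
    lights: tuple[LightSource, LightSource],
    structure: Structure,
    c_tot: float,
    path_length: float,
) -> tuple[float, float]:
    """Photostationary active fractions under both saturating lights for the
    candidate (X1, X2)."""
    n_c = structure.n_c
    kappa = beer_lambert_scale(c_tot, path_length) * n_c
    coord_A = x[0] + (x[1] - x[0]) * n_c
    fractions = []
    for light in lights:
        s_I, s_A = _clipped_rate_sums(x[0], coord_A, _light_basis(pair, light))
        k_I = phi.phi_I * s_I / kappa
        k_A = phi.phi_A * s_A / kappa
        fractions.append(_stationary_fraction(k_I, k_A, reversion, structure))
    return fractions[0], fractions[1]


def _x_from_fractions(c_act: float, c_inact: float) -> np.ndarray:
    d = c_inact - c_act
    if d == 0.0:
        raise SearchSpaceError("saturated fractions coincide; X is undetermined")
    return np.array([-c_act / d, (1.0 - c_act) / d])


def solve_X(
    phi: QuantumYields,
    pair: SaturatedPair,
    reversion: ReversionModel,
    lights: tuple[LightSource, LightSource],
    *,
    c_tot: float,
    path_length: float,
    structure: Structure = Structure.MONOMER,
    x0: tuple[float, float] = (1.0, 0.0),
    tol: float = 1e-9,
    max_iter: int = 500,
    damping: float = 0.5,
) -> tuple[float, float]:
    """Solve the implicit self-consistency equations for (X1, X2).

    Damped fixed-point iteration (each pass recomputes the photostationary
    fractions from the candidate spectra and maps them back to X), with the
    step shrunk adaptively when the residual grows and a 2-D root finder on
    the residuals as the final fallback.  Raises :class:`SearchSpaceError`
    with the last residual if nothing converges to ``tol``.
    """

    n_c = structure.n_c
    kappa = beer_lambert_scale(c_tot, path_length) * n_c
    bases = [_light_basis(pair, light) for light in lights]

    def fractions(x: np.ndarray) -> tuple[float, float]:
        coord_A = x[0] + (x[1] - x[0]) * n_c
        out = []
        for basis in bases:
            s_I, s_A = _clipped_rate_sums(x[0], coord_A, basis)
            k_I = phi.phi_I * s_I / kappa
            k_A = phi.phi_A * s_A / kappa
            out.append(_stationary_fraction(k_I, k_A, reversion, structure))
        return out[0], out[1]

    def residual(x: np.ndarray) -> np.ndarray:
        c_act, c_inact = fractions(x)
        return np.array(
            [x[0] + (x[1] - x[0]) * c_act, x[0] + (x[1] - x[0]) * c_inact - 1.0]
        )

    x = np.asarray(x0, dtype=float)
    step = damping
    last_res = np.inf
    for _ in range(max_iter):
        try:
            c_act, c_inact = fractions(x)
            x_new = _x_from_fractions(c_act, c_inact)
        except Exception as exc:
            raise SearchSpaceError(f"fixed-point step failed: {exc}") from exc
        r = np.array(
            [x[0] + (x[1] - x[0]) * c_act, x[0] + (x[1] - x[0]) * c_inact - 1.0]
        )
        res = float(np.abs(r).max())
        if res < tol:
            return float(x[0]), float(x[1])
        if res > last_res:  # overshooting: damp harder
            step = max(0.25 * step, 0.05)
        last_res = res
        x = (1.0 - step) * x + step * x_new
        if not np.all(np.isfinite(x)) or np.abs(x).max() > 1e8:
            raise SearchSpaceError("fixed-point iterates diverged")

    sol = root(residual, x, method="hybr", tol=tol * 1e-2)
    r = residual(sol.x)
    if np.abs(r).max() < tol:
        return float(sol.x[0]), float(sol.x[1])
    raise SearchSpaceError(
        f"implicit X-equations did not converge: last residual {np.abs(r).max():.3e}"
    )


def effective_beta(model: PhotoreceptorModel, light: LightSource) -> float:
    """Effective single reversion rate at the photostationary state.

    Defined so the single-pool steady-state formula reproduces the aggregate
    per-chromophore active fraction f of the full pool/dimer system under the
    given light: beta_eff = k_I/f - (k_I + k_A).  Exact for a single pool.
    """
    k_I, k_A = photo_rates(model, light)
    f = steady_state(model, light).c_A / model.n_c
    if f <= 0:
        raise SearchSpaceError("no active population at photostationary state")
    return k_I / f - (k_I + k_A)


def compute_R(
    phi: QuantumYields,
    x: tuple[float, float],
    eps: tuple[np.ndarray, np.ndarray],
    beta: float,
    lights: tuple[LightSource, LightSource],
    wavelengths: np.ndarray,
    n_c: int = 1,
) -> tuple[float, float]:
    """(R, R^o): the quantum-yield ratio and its reversion-free upper value.

    ``eps`` are the unscaled (eps_I, eps_A) spectra; ``beta`` the (effective)
    thermal reversion rate in s^-1.  Both follow from the photostationary
    balance under the activating light: with S_k = sum eps_k z_act * 1e-6,

        R^o = (S_I/S_A) (-n_c (X2 - X1)/X1 - 1),   R = R^o - (beta/Phi_I)/S_A,

    which for monomers (n_c = 1) reduces to R^o = -(X2/X1)(S_I/S_A).
    """
    x1, x2 = x
    if x1 == 0.0:
        raise SearchSpaceError("X1 = 0: degenerate photoequilibrium, R undefined")
    eps_I, eps_A = eps
    s_I = photo_rate(wavelengths, eps_I, lights[0])
    s_A = photo_rate(wavelengths, eps_A, lights[0])
    if s_A == 0.0:
        raise SearchSpaceError("activating light does not excite the active state")
    r_o = (s_I / s_A) * (-n_c * (x2 - x1) / x1 - 1.0)
    r = r_o - (beta / phi.phi_I) / s_A
    return r, r_o


@dataclass(frozen=True)
class SearchSpace:
    """Tabulated (X1, X2, R, R^o) over a quantum-yield grid, plus inputs.

    Carries everything needed to re-solve the implicit equations at arbitrary
    Phi during optimisation (:meth:`solve_at`).  ``R_max`` is the numerical
    maximum of R^o over the convergent grid cells — the upper bound of the
    optimiser's R box.
    """

    phi_A_grid: np.ndarray
    phi_I_grid: np.ndarray
    X1: np.ndarray  # shape (n_phi_A, n_phi_I); NaN where non-convergent
    X2: np.ndarray
    R: np.ndarray
    R_o: np.ndarray
    R_max: float
    pair: SaturatedPair
    reversion: ReversionModel
    lights: tuple[LightSource, LightSource]
    c_tot: float
    path_length: float
    structure: Structure

    @property
    def n_failed(self) -> int:
        return int(np.isnan(self.X1).sum())

    def solve_at(
        self, phi: QuantumYields, x0: tuple[float, float] | None = None
    ) -> tuple[float, float]:
        if x0 is None:
            # warm start from the nearest tabulated convergent cell
            ia = int(np.argmin(np.abs(np.log(self.phi_A_grid) - math.log(phi.phi_A))))
            ii = int(np.argmin(np.abs(np.log(self.phi_I_grid) - math.log(phi.phi_I))))
            if np.isfinite(self.X1[ia, ii]):
                x0 = (float(self.X1[ia, ii]), float(self.X2[ia, ii]))
            else:
                x0 = (1.0, 0.0)
        return solve_X(
            phi,
            self.pair,
            self.reversion,
            self.lights,
            c_tot=self.c_tot,
            path_length=self.path_length,
            structure=self.structure,
            x0=x0,
        )

    def epsilon_at(self, phi: QuantumYields) -> tuple[np.ndarray, np.ndarray]:
        x = self.solve_at(phi)
        return epsilon_from_X(
            x, self.pair, self.c_tot, self.path_length, self.structure.n_c
        )


def build_search_space(
    pair: SaturatedPair,
    reversion: ReversionModel,
    lights: tuple[LightSource, LightSource],
    *,
    c_tot: float,
    path_length: float,
    structure: Structure = Structure.MONOMER,
    n_phi: int = 50,
    phi_min: float = 1e-3,
    max_failed_fraction: float = 0.5,
) -> SearchSpace:
    """Tabulate the implicit solution over a log-uniform (Phi_A, Phi_I) grid.

    Each cell stores (X1, X2) solving the implicit equations plus R and R^o;
    non-convergent cells are recorded as NaN.  Errors out if more than
    ``max_failed_fraction`` of the grid fails.
    """
    if n_phi < 10:
        raise SearchSpaceError("grid resolution must be at least 10 points per axis")
    grid = np.exp(np.linspace(math.log(phi_min), 0.0, n_phi))
    shape = (n_phi, n_phi)
    X1 = np.full(shape, np.nan)
    X2 = np.full(shape, np.nan)
    R = np.full(shape, np.nan)
    R_o = np.full(shape, np.nan)

    for ia, phi_a in enumerate(grid):
        for ii, phi_i in enumerate(grid):
            phi = QuantumYields(phi_a, phi_i)
            # warm starts: left neighbour, the cell above, then the pure-state
            # solution — keeps the convergence set stable under grid refinement
            starts: list[tuple[float, float]] = []
            if ii > 0 and np.isfinite(X1[ia, ii - 1]):
                starts.append((float(X1[ia, ii - 1]), float(X2[ia, ii - 1])))
            if ia > 0 and np.isfinite(X1[ia - 1, ii]):
                starts.append((float(X1[ia - 1, ii]), float(X2[ia - 1, ii])))
            starts.append((1.0, 0.0))
            for x0 in starts:
                try:
                    x = solve_X(
                        phi,
                        pair,
                        reversion,
                        lights,
                        c_tot=c_tot,
                        path_length=path_length,
                        structure=structure,
                        x0=x0,
                    )
                except Exception:
                    continue
                X1[ia, ii], X2[ia, ii] = x
                try:
                    eps = epsilon_from_X(x, pair, c_tot, path_length, structure.n_c)
                    # the physical (clipped) spectra also drive the kinetics,
                    # so they define the S-sums of the R bound
                    eps_phys = (np.clip(eps[0], 0.0, None), np.clip(eps[1], 0.0, None))
                    model = _model_from_eps(
                        eps[0], eps[1], phi, pair, reversion, structure, c_tot, path_length
                    )
                    beta_eff = effective_beta(model, lights[0])
                    R[ia, ii], R_o[ia, ii] = compute_R(
                        phi, x, eps_phys, beta_eff, lights, pair.wavelengths, structure.n_c
                    )
                except Exception:
                    pass
                break

    n_failed = int(np.isnan(X1).sum())
    if n_failed > max_failed_fraction * X1.size:
        raise SearchSpaceError(
            f"{n_failed}/{X1.size} grid cells failed to converge"
        )
    valid = np.isfinite(R_o) & (R_o > 0)
    if not np.any(valid):
        raise SearchSpaceError("no grid cell produced a positive R^o")
    return SearchSpace(
        phi_A_grid=grid,
        phi_I_grid=grid,
        X1=X1,
        X2=X2,
        R=R,
        R_o=R_o,
        R_max=float(R_o[valid].max()),
        pair=pair,
        reversion=reversion,
        lights=lights,
        c_tot=c_tot,
        path_length=path_length,
        structure=structure,
    )
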