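"""Step 3: chi-square fit of difference spectra over (Phi_A, R).

The decision variables are the activation quantum yield Phi_A in [0, 1] and
the quantum-yield ratio R = Phi_A/Phi_I in [0, R^max] (the bound supplied by
the search space).  For a candidate (Phi_A, R):

1. Phi_I = Phi_A / R;
2. the implicit equations give (X1, X2) and hence candidate extinction
   spectra eps_I, eps_A;
3. sigma = eps * Phi turns those into cross-sections;
4. the forward model simulates both measurement directions and the cost is

       chi^2 = sum_series sum_t sum_lambda ((D - S)/nu)^2,

   the squared mismatch of measured vs simulated difference spectra, weighted
   by the measurement errors nu (nu = 1 where no error estimate exists).

Local minimisation is bounded Nelder-Mead started from many seeded random points;
non-convergent search-space cells contribute a large finite penalty instead of
raising, so exploration survives pathological corners.  95 % confidence
intervals come from profile likelihoods with the chi^2(0.95, 1) = 3.8415
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2 as chi2_dist

from .kinetics import PhotoreceptorModel, QuantumYields
from .searchspace import SearchSpace, SearchSpaceError, _model_from_eps
from .spectra import SpectraSeries, difference_series, simulate_absorbance

__all__ = [
    "PL_THRESHOLD",
    "CHI2_PENALTY",
    "FitResult",
    "ProfileResult",
    "chi2_score",
    "fit",
    "profile_likelihood",
    "OptimizeError",
]

#: chi^2(0.95, 1), the profile-likelihood 95 % threshold.
PL_THRESHOLD = float(chi2_dist.ppf(0.95, 1))

#: finite cost assigned when the implicit solve fails at a candidate point.
CHI2_PENALTY = 1e12


class OptimizeError(RuntimeError):
    pass


def _candidate_model(
    phi: QuantumYields, space: SearchSpace
) -> tuple[PhotoreceptorModel, tuple[np.ndarray, np.ndarray]]:
    eps = space.epsilon_at(phi)
    model = _model_from_eps(
        eps[0],
        eps[1],
        phi,
        space.pair,
        space.reversion,
        space.structure,
        space.c_tot,
        space.path_length,
    )
    return model, eps


def _series_chi2(model: PhotoreceptorModel, series: SpectraSeries) -> float:
    sim = simulate_absorbance(model, series.prep, series.exp, series.times)
    d_data = difference_series(series)
    d_sim = difference_series(sim)
    mask = np.isfinite(series.times) & (series.times > 0)
    resid = d_data[mask] - d_sim[mask]
    if series.errors is None:
        nu = np.ones_like(resid)
    else:
        nu = series.errors[mask].copy()
        nu[nu == 0] = 1.0  # zero-signal points carry no information either way
    return float(np.sum((resid / nu) ** 2))


def chi2_score(
    phi_A: float,
    R: float,
    data: list[SpectraSeries],
    space: SearchSpace,
) -> float:
    """Eq.-(9)-style cost at one candidate point, summed over all series.

    Returns :data:`CHI2_PENALTY` when the implicit search-space solve fails,
    so multi-start optimisation can continue past pathological corners.
    """
    if not (phi_A > 0 and R > 0):
        return CHI2_PENALTY
    phi_I = phi_A / R
    if phi_I > 1.0:
        # unphysical inactive yield: finite penalty keeps the box explorable
        return CHI2_PENALTY
    try:
        phi = QuantumYields(phi_A, phi_I)
    except Exception:
        return CHI2_PENALTY
    try:
        model, _ = _candidate_model(phi, space)
        return sum(_series_chi2(model, s) for s in data)
    except Exception:
        return CHI2_PENALTY


@dataclass(frozen=True)
class ProfileResult:
    param: str
    values: np.ndarray
    delta_chi2: np.ndarray
    ci95: tuple[float, float]
    at_bound: tuple[bool, bool]


@dataclass
class FitResult:
    """Optimum of the multi-start fit plus everything needed downstream."""

    phi_A: float
    phi_I: float
    R: float
    chi2: float
    wavelengths: np.ndarray
    epsilon_I: np.ndarray
    epsilon_A: np.ndarray
    sigma_I: np.ndarray
    sigma_A: np.ndarray
    X: tuple[float, float]
    starts: list[dict]
    space: SearchSpace
    data: list[SpectraSeries]
    seed: int | None = None
    profiles: dict[str, ProfileResult] = field(default_factory=dict)

    @property
    def yields(self) -> QuantumYields:
        return QuantumYields(self.phi_A, self.phi_I)

    @property
    def ci95(self) -> dict[str, tuple[float, float]]:
        return {name: p.ci95 for name, p in self.profiles.items()}


def _draw_starts(rng: np.random.Generator, n: int, r_max: float) -> np.ndarray:
    """Alternating uniform / log-uniform draws of R (Phi_A always uniform).

    R^max can be orders of magnitude above plausible ratios, so purely uniform
    draws would almost never start near small R; alternating with log-uniform
    draws covers every scale of the box.
    """
    r_lo = min(1e-3, r_max / 10)
    starts = np.empty((n, 2))
    starts[:, 0] = rng.uniform(0.0, 1.0, size=n)
    uni = rng.uniform(r_lo, r_max, size=n)
    logu = np.exp(rng.uniform(math.log(r_lo), math.log(r_max), size=n))
    starts[:, 1] = np.where(np.arange(n) % 2 == 0, uni, logu)
    return starts


def fit(
    data: list[SpectraSeries],
    space: SearchSpace,
    n_starts: int = 100,
    seed: int | None = 0,
    ftol: float = 1e-12,
) -> FitResult:
    """Multi-start bounded minimisation of the chi-square over (Phi_A, R).

    The local optimiser is bounded Nelder-Mead: the objective carries tiny
    numerical noise from the inner implicit solve (tolerance 1e-9), which
    derivative-free descent tolerates where finite-difference gradients
    do not.
    """
    r_max = space.R_max
    rng = np.random.default_rng(seed)
    starts = _draw_starts(rng, n_starts, r_max)

    def objective(xy: np.ndarray) -> float:
        return chi2_score(xy[0], xy[1], data, space)

    bounds = [(1e-6, 1.0), (1e-6, r_max)]
    records: list[dict] = []
    best = None
    for x0 in starts:
        try:
            sol = minimize(
                objective,
                x0,
                method="Nelder-Mead",
                bounds=bounds,
                options={"xatol": 1e-9, "fatol": ftol, "maxiter": 1000},
            )
        except Exception:
            continue
        records.append(
            {"x0": tuple(x0), "x": tuple(sol.x), "chi2": float(sol.fun), "success": bool(sol.success)}
        )
        if best is None or sol.fun < best.fun:
            best = sol
    if best is None or best.fun >= CHI2_PENALTY:
        raise OptimizeError("all optimisation starts failed")

    phi_A, r = float(best.x[0]), float(best.x[1])
    phi_I = phi_A / r
    phi = QuantumYields(phi_A, min(phi_I, 1.0))
    x = space.solve_at(phi)
    from .searchspace import epsilon_from_X

    eps_I, eps_A = epsilon_from_X(
        x, space.pair, space.c_tot, space.path_length, space.structure.n_c
    )
    return FitResult(
        phi_A=phi_A,
        phi_I=phi_I,
        R=r,
        chi2=float(best.fun),
        wavelengths=space.pair.wavelengths,
        epsilon_I=eps_I,
        epsilon_A=eps_A,
        sigma_I=eps_I * phi.phi_I,
        sigma_A=eps_A * phi.phi_A,
        X=x,
        starts=records,
        space=space,
        data=list(data),
        seed=seed,
    )


def _profiled_chi2(
    param: str, value: float, result: FitResult
) -> float:
    """Re-optimise the remaining free parameter with ``param`` fixed."""
    data, space = result.data, result.space
    r_max = space.R_max

    if param == "phi_A":
        def inner(r):
            return chi2_score(value, r, data, space)

        lo, hi = 1e-6, r_max
        guess = result.R
    elif param == "R":
        def inner(a):
            return chi2_score(a, value, data, space)

        lo, hi = 1e-6, 1.0
        guess = result.phi_A
    elif param == "phi_I":
        # fixed Phi_I: free parameter is Phi_A with R = Phi_A / Phi_I
        def inner(a):
            return chi2_score(a, a / value, data, space)

        lo, hi = 1e-6, min(1.0, r_max * value)
        guess = result.phi_A
    else:
        raise OptimizeError(f"unknown parameter {param!r}")

    if hi <= lo:
        return CHI2_PENALTY
    # a local bracket around the previous optimum plus the full box, so the
    # profiled curve tracks the relevant branch without missing far minima
    lo_local = max(lo, min(guess * 0.5, guess - 0.1 * (hi - lo)))
    hi_local = min(hi, max(guess * 2.0, guess + 0.1 * (hi - lo)))
    best = math.inf
    for lo_b, hi_b in ((lo_local, hi_local), (lo, hi)):
        if hi_b <= lo_b:
            continue
        sol = minimize_scalar(
            inner, bounds=(lo_b, hi_b), method="bounded", options={"xatol": 1e-10}
        )
        best = min(best, float(sol.fun))
    return best


def profile_likelihood(
    result: FitResult,
    param: str,
    grid: np.ndarray | None = None,
    n_grid: int = 101,
    span: float = 0.5,
) -> ProfileResult:
    """Profile likelihood of ``phi_A``, ``phi_I`` or ``R`` around the optimum.

    For each grid value the other parameter is re-optimised; the 95 % CI is
    the connected region around the optimum where the chi-square exceeds its
    minimum by at most chi^2(0.95, 1) = 3.8415.  A CI edge lying on the grid
    boundary is flagged one-sided.
    """
    centre = {"phi_A": result.phi_A, "phi_I": result.phi_I, "R": result.R}[param]
    if grid is None:
        grid = np.linspace(centre * (1 - span), centre * (1 + span), n_grid)
        grid = grid[grid > 0]
    # the optimum itself is always a scan point, so its Delta-chi2 ~ 0 cell
    # anchors the connected region even on coarse grids
    grid = np.unique(np.append(np.asarray(grid, dtype=float), centre))
    curve = np.array([_profiled_chi2(param, v, result) for v in grid])
    delta = curve - result.chi2
    delta = np.where(delta < 0, 0.0, delta)  # numerical floor at the optimum

    inside = delta <= PL_THRESHOLD
    i_centre = int(np.argmin(np.abs(grid - centre)))
    if not inside[i_centre]:
        # optimum grid cell itself should be inside: fall back to argmin
        i_centre = int(np.argmin(delta))
    lo_i = i_centre
    while lo_i > 0 and inside[lo_i - 1]:
        lo_i -= 1
    hi_i = i_centre
    while hi_i < grid.size - 1 and inside[hi_i + 1]:
        hi_i += 1

    def crossing(i_in: int, i_out: int) -> float:
        # linear interpolation of delta-chi2 across the threshold
        d0, d1 = delta[i_in], delta[i_out]
        if d1 == d0:
            return grid[i_out]
        w = (PL_THRESHOLD - d0) / (d1 - d0)
        return float(grid[i_in] + w * (grid[i_out] - grid[i_in]))

    at_lo = lo_i == 0
    at_hi = hi_i == grid.size - 1
    lo_val = grid[0] if at_lo else crossing(lo_i, lo_i - 1)
    hi_val = grid[-1] if at_hi else crossing(hi_i, hi_i + 1)

    prof = ProfileResult(
        param=param,
        values=grid,
        delta_chi2=delta,
        ci95=(lo_val, hi_val),
        at_bound=(at_lo, at_hi),
    )
    result.profiles[param] = prof
    return prof
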