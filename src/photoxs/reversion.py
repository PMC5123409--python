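"""Step 1: thermal-reversion rates from dark-decay absorbance data.

After a saturating period of activating light the sample sits in darkness and
the active population decays thermally.  The normalised decay

    E(t) = (A(lambda, t) - A(lambda, inf)) / (A(lambda, 0) - A(lambda, inf))

is independent of the wavelength used to compute it, starts at 1 and decays as
a sum of exponentials ``sum_j alpha_j exp(-beta_j t)`` with ``sum_j alpha_j = 1``
— one term per reversion pool.  This module extracts E(t) from a dark series
and fits the one- or two-pool model with multi-start bounded least squares,
reporting profile-likelihood 95 % confidence intervals and AICc for both model
orders (the choice between them is deliberately left to the user).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist

from .kinetics import ReversionModel, ReversionPool
from .spectra import SpectraSeries, SpectraError

__all__ = [
    "DecayDataset",
    "ReversionFit",
    "normalise_decay",
    "fit_exponentials",
    "ReversionError",
]

#: chi^2(0.95, 1): profile-likelihood threshold for a 95 % CI on one parameter.
PL_THRESHOLD = float(chi2_dist.ppf(0.95, 1))


class ReversionError(ValueError):
    pass


@dataclass(frozen=True)
class DecayDataset:
    """Normalised dark decay E(t), dimensionless, with E(0) = 1 (up to noise)."""

    times: np.ndarray
    decay: np.ndarray
    wavelengths_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.decay, dtype=float)
        if t.shape != e.shape or t.ndim != 1:
            raise ReversionError("times and decay must be matching 1-D arrays")
        if np.any(~np.isfinite(t)):
            raise ReversionError("decay times must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "decay", e)


def normalise_decay(
    series: SpectraSeries,
    lambda_select: np.ndarray | None = None,
    n_auto: int = 5,
) -> DecayDataset:
    """Normalised percentage decrease of active photoreceptor from a dark series.

    Requires the series to contain a t = 0 spectrum and a t -> inf plateau.
    ``lambda_select`` picks the wavelengths over which the per-wavelength
    ratios are averaged; by default the ``n_auto`` bins with the largest
    |A(0) - A(inf)| (best signal-to-noise) are used.
    """
    try:
        a0 = series.at_time(0.0)
        a_inf = series.saturation
    except SpectraError as exc:
        raise ReversionError(
            "dark series must include t = 0 and a t -> inf plateau spectrum"
        ) from exc
    span = a0 - a_inf
    if lambda_select is None:
        idx = np.argsort(np.abs(span))[::-1][:n_auto]
    else:
        lam = np.asarray(lambda_select, dtype=float)
        idx = np.nonzero(np.isin(series.wavelengths, lam))[0]
        if idx.size == 0:
            raise ReversionError("none of the selected wavelengths are on the grid")
    if np.allclose(span[idx], 0.0):
        raise ReversionError("no dark dynamics: A(0) equals A(inf) at all selected wavelengths")
    finite = series.finite_mask
    ratios = (series.absorbance[finite][:, idx] - a_inf[idx]) / span[idx]
    return DecayDataset(
        times=series.times[finite],
        decay=ratios.mean(axis=1),
        wavelengths_used=series.wavelengths[idx],
    )


def _decay_model(params: np.ndarray, t: np.ndarray, n_pools: int) -> np.ndarray:
    if n_pools == 1:
        return np.exp(-params[0] * t)
    alpha1, beta1, beta2 = params
    return alpha1 * np.exp(-beta1 * t) + (1.0 - alpha1) * np.exp(-beta2 * t)


@dataclass(frozen=True)
class ReversionFit:
    """A fitted reversion model with per-parameter 95 % CIs and diagnostics."""

    model: ReversionModel
    chi2: float
    aicc: float
    n_pools: int
    ci95: dict[str, tuple[float, float]]
    at_boundary: bool
    n_starts: int

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return sum(p.alpha * np.exp(-p.beta * t) for p in self.model.pools)


def _aicc(ssr: float, n: int, k: int) -> float:
    if n <= k + 1:
        return math.inf
    ssr = max(ssr, 1e-300)
    return n * math.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _profile_ci(
    cost,
    fit_params: np.ndarray,
    index: int,
    bounds: tuple[np.ndarray, np.ndarray],
    best: float,
    positive: bool,
) -> tuple[tuple[float, float], bool]:
    """Scan one parameter away from its estimate until the profiled cost
    exceeds best + chi^2(0.95, 1); re-optimises the remaining parameters at
    every scan point.  Multiplicative steps for rate-like (positive)
    parameters, additive for fractions."""
    lo_b, hi_b = bounds
    free = [i for i in range(fit_params.size) if i != index]

    def profiled(value: float) -> float:
        if free:
            def resid(sub):
                full = fit_params.copy()
                full[index] = value
                full[free] = sub
                return cost(full)

            sol = least_squares(
                resid,
                fit_params[free],
                bounds=(lo_b[free], hi_b[free]),
                method="trf",
            )
            return float(2.0 * sol.cost)
        full = fit_params.copy()
        full[index] = value
        r = cost(full)
        return float(r @ r)

    def scan(direction: int) -> tuple[float, bool]:
        value = fit_params[index]
        for _ in range(60):
            if positive and value > 0:
                value = value * (1.25 if direction > 0 else 0.8)
            else:
                step = 0.02 * max(abs(fit_params[index]), 0.05)
                value = value + direction * step
            if value <= lo_b[index] or value >= hi_b[index]:
                return float(np.clip(value, lo_b[index], hi_b[index])), True
            if profiled(value) > best + PL_THRESHOLD:
                return value, False
        return value, True

    hi, hit_hi = scan(+1)
    lo, hit_lo = scan(-1)
    return (lo, hi), (hit_lo or hit_hi)


def fit_exponentials(
    data: DecayDataset,
    n_pools: int = 1,
    n_starts: int = 20,
    seed: int = 0,
) -> ReversionFit:
    """Fit ``sum_j alpha_j exp(-beta_j t)`` with ``sum alpha_j = 1`` enforced.

    For ``n_pools = 2`` the free parameters are (alpha_1, beta_1, beta_2) with
    alpha_2 = 1 - alpha_1 and the label-switching tie broken by requiring
    beta_1 >= beta_2.  Initial rates are drawn log-uniformly over
    [1e-7, 1] s^-1 from a seeded generator.
    """
    if n_pools not in (1, 2):
        raise ReversionError("n_pools must be 1 or 2")
    t, e = data.times, data.decay
    if t.size < 2 * n_pools + 1:
        raise ReversionError(
            f"need at least {2 * n_pools + 1} time points for {n_pools} pool(s)"
        )

    def cost(params: np.ndarray) -> np.ndarray:
        return _decay_model(params, t, n_pools) - e

    rng = np.random.default_rng(seed)
    if n_pools == 1:
        lo = np.array([0.0])
        hi = np.array([np.inf])
    else:
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([1.0, np.inf, np.inf])

    best = None
    for _ in range(n_starts):
        beta0 = 10.0 ** rng.uniform(-7, 0, size=n_pools)
        if n_pools == 1:
            x0 = beta0
        else:
            x0 = np.array([rng.uniform(0.2, 0.8), beta0.max(), beta0.min()])
        try:
            sol = least_squares(cost, x0, bounds=(lo, hi), method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ReversionError("exponential fit failed to converge from any start")

    params = best.x.copy()
    if n_pools == 2 and params[1] < params[2]:
        params = np.array([1.0 - params[0], params[2], params[1]])
    ssr = float(2.0 * best.cost)

    if n_pools == 1:
        pools = (ReversionPool(1.0, float(params[0])),)
        names = ["beta_1"]
        positive = [True]
    else:
        pools = (
            ReversionPool(float(params[0]), float(params[1])),
            ReversionPool(float(1.0 - params[0]), float(params[2])),
        )
        names = ["alpha_1", "beta_1", "beta_2"]
        positive = [False, True, True]

    ci95: dict[str, tuple[float, float]] = {}
    at_boundary = any(p.beta <= 1e-12 for p in pools)
    for i, name in enumerate(names):
        ci, hit = _profile_ci(cost, params, i, (lo, hi), ssr, positive[i])
        ci95[name] = ci
        at_boundary = at_boundary or hit

    return ReversionFit(
        model=ReversionModel(pools),
        chi2=ssr,
        aicc=_aicc(ssr, t.size, len(names)),
        n_pools=n_pools,
        ci95=ci95,
        at_boundary=at_boundary,
        n_starts=n_starts,
    )
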