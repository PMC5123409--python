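"""Two-state photoreceptor photocycle kinetics under piecewise-constant light.

A photoreceptor population switches between an inactive state ``P_I`` and an
active state ``P_A``.  Light drives both directions: the activation rate is
``k_I = sum_lambda sigma_I^lambda z^lambda`` (the inactive state absorbs and
converts) and the deactivation rate is ``k_A`` built from ``sigma_A``.  Thermal
reversion returns ``P_A`` to ``P_I`` in darkness at rate(s) ``beta``.

Conventions
-----------
* spectral photon fluence ``z`` in umol m^-2 s^-1 per 1-nm bin,
* photoconversion cross-sections ``sigma`` in m^2 mol^-1,
* photochemical rates carry the factor 1e-6 (umol -> mol photons) so that
  sigma ~ 1e4 m^2 mol^-1 under 11 umol m^-2 s^-1 light gives switching on the
  0.1 s^-1 scale (minutes to saturation), matching in-vitro phytochrome data.

Populations with several thermal-reversion rates are modelled as static pools:
a fraction ``alpha_j`` of the molecules shares the cross-sections and quantum
yields but reverts with its own ``beta_j``; pools do not exchange molecules, so
the dark decay of the total active fraction is exactly
``sum_j alpha_j exp(-beta_j t)``.  Dimers are modelled as two independent
protomers per molecule (species AA, AI, II) whose homo- and hetero-dimer
reversion rates may differ.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PHOTON_UNIT",
    "DARK",
    "LightSource",
    "LightPhase",
    "LightProtocol",
    "CrossSectionSet",
    "QuantumYields",
    "ReversionPool",
    "ReversionModel",
    "Structure",
    "PhotoreceptorModel",
    "StateFractions",
    "photo_rate",
    "photo_rates",
    "steady_state",
    "propagate",
    "dark_adapted_state",
    "active_adapted_state",
    "KineticsError",
]

#: umol photons -> mol photons, so rates land in s^-1.
PHOTON_UNIT = 1e-6

#: Sentinel for darkness in a :class:`LightPhase`.
DARK = None


class KineticsError(ValueError):
    """Raised for invalid kinetic inputs (bad grids, degenerate systems)."""


def _as_grid(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise KineticsError("wavelength grid must be a non-empty 1-D array")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise KineticsError("wavelength grid must be strictly increasing")
    return arr


@dataclass(frozen=True)
class LightSource:
    """A wavelength-gridded spectral photon fluence (umol m^-2 s^-1 per bin)."""

    wavelengths: np.ndarray
    fluence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", _as_grid(self.wavelengths))
        flu = np.asarray(self.fluence, dtype=float)
        if flu.shape != self.wavelengths.shape:
            raise KineticsError("fluence and wavelength grids differ in shape")
        if np.any(flu < 0):
            raise KineticsError("fluence must be non-negative")
        object.__setattr__(self, "fluence", flu)

    @property
    def total_fluence(self) -> float:
        """Total photon fluence rate: the sum over bins."""
        return float(self.fluence.sum())


@dataclass(frozen=True)
class LightPhase:
    """One segment of a light protocol: a duration and a source (or DARK).

    ``duration = math.inf`` means "until saturation" (photostationary state).
    """

    duration: float
    source: LightSource | None = DARK

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise KineticsError(f"phase duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class LightProtocol:
    """An ordered sequence of light phases (preparatory or experimental)."""

    phases: tuple[LightPhase, ...]

    def __post_init__(self) -> None:
        phases = tuple(self.phases)
        if not phases:
            raise KineticsError("protocol must contain at least one phase")
        object.__setattr__(self, "phases", phases)

    @classmethod
    def saturating(cls, source: LightSource | None) -> "LightProtocol":
        return cls((LightPhase(math.inf, source),))

    @classmethod
    def constant(cls, source: LightSource | None, duration: float = math.inf) -> "LightProtocol":
        return cls((LightPhase(duration, source),))

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))


@dataclass(frozen=True)
class CrossSectionSet:
    """Photoconversion cross-sections of both states on a common grid (m^2 mol^-1)."""

    wavelengths: np.ndarray
    sigma_I: np.ndarray
    sigma_A: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", _as_grid(self.wavelengths))
        for name in ("sigma_I", "sigma_A"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.wavelengths.shape:
                raise KineticsError(f"{name} does not match the wavelength grid")
            if np.any(arr < 0):
                raise KineticsError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class QuantumYields:
    """Quantum yields of the two photoconversions, each in (0, 1]."""

    phi_A: float
    phi_I: float

    def __post_init__(self) -> None:
        for name, val in (("phi_A", self.phi_A), ("phi_I", self.phi_I)):
            if not (0 < val <= 1):
                raise KineticsError(f"{name} must lie in (0, 1], got {val}")

    @property
    def R(self) -> float:
        """Quantum-yield ratio R = phi_A / phi_I."""
        return self.phi_A / self.phi_I


@dataclass(frozen=True)
class ReversionPool:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1):
            raise KineticsError(f"pool fraction must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise KineticsError(f"reversion rate must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class ReversionModel:
    """Thermal reversion: pool fractions alpha_j (summing to 1) and rates beta_j."""

    pools: tuple[ReversionPool, ...]

    def __post_init__(self) -> None:
        pools = tuple(
            p if isinstance(p, ReversionPool) else ReversionPool(*p) for p in self.pools
        )
        if not pools:
            raise KineticsError("at least one reversion pool is required")
        total = sum(p.alpha for p in pools)
        if abs(total - 1.0) > 1e-12:
            raise KineticsError(f"pool fractions must sum to 1, got {total}")
        object.__setattr__(self, "pools", pools)

    @classmethod
    def single(cls, beta: float) -> "ReversionModel":
        return cls((ReversionPool(1.0, beta),))

    @property
    def alphas(self) -> np.ndarray:
        return np.array([p.alpha for p in self.pools])

    @property
    def betas(self) -> np.ndarray:
        return np.array([p.beta for p in self.pools])

    @property
    def mean_beta(self) -> float:
        return float(self.alphas @ self.betas)


class Structure(enum.Enum):
    MONOMER = 1
    DIMER = 2

    @property
    def n_c(self) -> int:
        """Chromophores per photoreceptor molecule."""
        return self.value


@dataclass(frozen=True)
class PhotoreceptorModel:
    """Everything needed to simulate a sample: photochemistry, reversion, optics.

    For ``Structure.DIMER`` the reversion pools are reinterpreted: the first
    pool's rate is the per-protomer reversion rate of the AA homo-dimer and the
    last pool's that of the AI hetero-dimer (pool weights are not used — the
    dimer species mix dynamically rather than forming static pools).
    """

    cross_sections: CrossSectionSet
    yields: QuantumYields
    reversion: ReversionModel
    structure: Structure = Structure.MONOMER
    c_tot: float = 0.34 / 70000.0  # mol L^-1 (0.34 mg/ml of a 70 kDa protein)
    path_length: float = 1.06  # cm, path-corrected 1-cm cuvette

    def __post_init__(self) -> None:
        if self.c_tot <= 0:
            raise KineticsError("c_tot must be positive")
        if self.path_length <= 0:
            raise KineticsError("path length must be positive")

    @property
    def n_c(self) -> int:
        return self.structure.n_c

    @property
    def wavelengths(self) -> np.ndarray:
        return self.cross_sections.wavelengths

    @property
    def epsilon_I(self) -> np.ndarray:
        """Extinction coefficient of P_I: eps = sigma / phi (m^2 mol^-1)."""
        return self.cross_sections.sigma_I / self.yields.phi_I

    @property
    def epsilon_A(self) -> np.ndarray:
        return self.cross_sections.sigma_A / self.yields.phi_A

    @property
    def beta_AA(self) -> float:
        return self.reversion.pools[0].beta

    @property
    def beta_AI(self) -> float:
        return self.reversion.pools[-1].beta


@dataclass(frozen=True)
class StateFractions:
    """Population state at one instant.

    For monomers ``values`` holds the within-pool active fractions ``a_j`` (one
    per reversion pool) and ``alphas`` the static pool weights; the aggregate
    active fraction is ``c_A = sum_j alpha_j a_j``.  For dimers ``values`` holds
    the dimer-species probabilities ``(p_II, p_AI, p_AA)`` and
    ``c_A = p_AI + 2 p_AA``.  Conservation ``c_A + c_I = n_c`` holds by
    construction.
    """

    structure: Structure
    values: np.ndarray
    alphas: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.structure is Structure.MONOMER:
            if self.alphas is None:
                raise KineticsError("monomer state requires pool weights")
            object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
            if self.alphas.shape != vals.shape:
                raise KineticsError("pool weights and fractions differ in shape")
        else:
            if vals.shape != (3,):
                raise KineticsError("dimer state requires (p_II, p_AI, p_AA)")

    @classmethod
    def monomer(cls, active: Sequence[float], alphas: Sequence[float]) -> "StateFractions":
        return cls(Structure.MONOMER, np.asarray(active, float), np.asarray(alphas, float))

    @classmethod
    def dimer(cls, p_II: float, p_AI: float, p_AA: float) -> "StateFractions":
        return cls(Structure.DIMER, np.array([p_II, p_AI, p_AA]))

    @property
    def n_c(self) -> int:
        return self.structure.n_c

    @property
    def c_A(self) -> float:
        if self.structure is Structure.MONOMER:
            return float(self.alphas @ self.values)
        p_II, p_AI, p_AA = self.values
        return float(p_AI + 2.0 * p_AA)

    @property
    def c_I(self) -> float:
        return self.n_c - self.c_A


def photo_rate(
    wavelengths: Sequence[float],
    sigma: Sequence[float],
    light: LightSource | None,
    *,
    interpolate: bool = True,
) -> float:
    """Photochemical rate sum_lambda sigma^lambda z^lambda * 1e-6, in s^-1.

    ``sigma`` may be any per-wavelength channel (a cross-section or an
    extinction coefficient).  If the light lives on a different grid the
    channel is linearly interpolated onto the light's grid (zero outside its
    support), preserving the light's total fluence.  ``DARK`` gives 0.
    """
    if light is DARK:
        return 0.0
    wl = np.asarray(wavelengths, dtype=float)
    sig = np.asarray(sigma, dtype=float)
    if wl.shape != sig.shape:
        raise KineticsError("sigma does not match its wavelength grid")
    if wl.shape == light.wavelengths.shape and np.array_equal(wl, light.wavelengths):
        channel = sig
    elif interpolate:
        channel = np.interp(light.wavelengths, wl, sig, left=0.0, right=0.0)
    else:
        raise KineticsError("light and channel grids differ and interpolation is disabled")
    return float(channel @ light.fluence) * PHOTON_UNIT


def photo_rates(model: PhotoreceptorModel, light: LightSource | None) -> tuple[float, float]:
    """(k_I, k_A): activation and deactivation rates of ``model`` under ``light``."""
    cs = model.cross_sections
    k_I = photo_rate(cs.wavelengths, cs.sigma_I, light)
    k_A = photo_rate(cs.wavelengths, cs.sigma_A, light)
    return k_I, k_A


def _dimer_generator(k_I: float, k_A: float, beta_AA: float, beta_AI: float) -> np.ndarray:
    """Rate matrix of the (II, AI, AA) chain, columns = source species.

    Independent-protomer stoichiometry: activation II->AI at 2 k_I, AI->AA at
    k_I; deactivation AA->AI at 2 k_A, AI->II at k_A; thermal reversion
    AA->AI at 2 beta_AA and AI->II at beta_AI.
    """
    up0 = 2.0 * k_I
    up1 = k_I
    dn1 = k_A + beta_AI
    dn2 = 2.0 * (k_A + beta_AA)
    return np.array(
        [
            [-up0, dn1, 0.0],
            [up0, -(up1 + dn1), dn2],
            [0.0, up1, -dn2],
        ]
    )


def _dimer_stationary(k_I: float, k_A: float, beta_AA: float, beta_AI: float) -> np.ndarray:
    """Stationary (p_II, p_AI, p_AA) of the birth-death chain (detailed balance)."""
    up0, up1 = 2.0 * k_I, k_I
    dn1, dn2 = k_A + beta_AI, 2.0 * (k_A + beta_AA)
    if up0 == 0.0:  # no activation channel: everything drains to II
        if dn1 == 0.0 and dn2 == 0.0:
            raise KineticsError("no dynamics: all rates are zero")
        return np.array([1.0, 0.0, 0.0])
    if dn1 == 0.0 or dn2 == 0.0:  # no deactivation: everything ends fully active
        return np.array([0.0, 0.0, 1.0])
    r1 = up0 / dn1
    r2 = r1 * up1 / dn2
    z = 1.0 + r1 + r2
    return np.array([1.0, r1, r2]) / z


def steady_state(model: PhotoreceptorModel, light: LightSource | None) -> StateFractions:
    """Photostationary state under constant ``light`` (or dark steady state).

    Monomer pools: ``a_j = k_I / (k_I + k_A + beta_j)`` per pool.  Dimers: the
    stationary distribution of the (II, AI, AA) transition chain.
    """
    k_I, k_A = photo_rates(model, light)
    if model.structure is Structure.DIMER:
        return StateFractions.dimer(*_dimer_stationary(k_I, k_A, model.beta_AA, model.beta_AI))
    betas = model.reversion.betas
    denoms = k_I + k_A + betas
    if np.all(denoms == 0):
        raise KineticsError("no dynamics: all rates are zero")
    active = np.zeros_like(betas)
    nz = denoms > 0
    active[nz] = k_I / denoms[nz]
    if np.any(~nz):
        # a pool with no reactions at all has no defined steady state
        raise KineticsError("dark steady state undefined for a pool with beta = 0")
    return StateFractions.monomer(active, model.reversion.alphas)


def dark_adapted_state(model: PhotoreceptorModel) -> StateFractions:
    """Fully inactive population (c_A = 0)."""
    if model.structure is Structure.DIMER:
        return StateFractions.dimer(1.0, 0.0, 0.0)
    zeros = np.zeros(len(model.reversion.pools))
    return StateFractions.monomer(zeros, model.reversion.alphas)


def active_adapted_state(model: PhotoreceptorModel) -> StateFractions:
    """Fully active population (c_A = n_c)."""
    if model.structure is Structure.DIMER:
        return StateFractions.dimer(0.0, 0.0, 1.0)
    ones = np.ones(len(model.reversion.pools))
    return StateFractions.monomer(ones, model.reversion.alphas)


def _propagate_phase(
    model: PhotoreceptorModel, state: StateFractions, phase: LightPhase, t: float
) -> StateFractions:
    """State after time ``t`` (may be inf) spent in ``phase``."""
    k_I, k_A = photo_rates(model, phase.source)
    if model.structure is Structure.DIMER:
        q = _dimer_generator(k_I, k_A, model.beta_AA, model.beta_AI)
        if not np.any(q):
            return state  # darkness with beta = 0: nothing moves
        if math.isinf(t):
            return StateFractions.dimer(
                *_dimer_stationary(k_I, k_A, model.beta_AA, model.beta_AI)
            )
        p = expm(q * t) @ state.values
        p = np.clip(p, 0.0, None)
        return StateFractions.dimer(*(p / p.sum()))
    betas = model.reversion.betas
    denoms = k_I + k_A + betas
    a0 = state.values
    a = np.empty_like(a0)
    nz = denoms > 0
    a_inf = np.zeros_like(a0)
    a_inf[nz] = k_I / denoms[nz]
    if math.isinf(t):
        a[nz] = a_inf[nz]
    else:
        a[nz] = a_inf[nz] + (a0[nz] - a_inf[nz]) * np.exp(-denoms[nz] * t)
    a[~nz] = a0[~nz]  # darkness with beta = 0: constant
    return StateFractions.monomer(a, model.reversion.alphas)


def propagate(
    model: PhotoreceptorModel,
    protocol: LightProtocol,
    c0: StateFractions | None = None,
    times: Sequence[float] | None = None,
) -> StateFractions | list[StateFractions]:
    """Propagate ``c0`` through the protocol's phases.

    With ``times=None`` returns the state at the end of the protocol.  With a
    sequence of times (seconds from protocol start, non-decreasing) returns the
    state at each requested time; a time beyond the protocol's total duration
    holds the final phase's light.  Monomer phases use the per-pool closed
    form; dimer phases integrate the linear (II, AI, II) system exactly via
    the matrix exponential.
    """
    if c0 is None:
        c0 = dark_adapted_state(model)
    if times is None:
        state = c0
        for phase in protocol.phases:
            state = _propagate_phase(model, state, phase, phase.duration)
        return state

    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise KineticsError("requested times must be >= 0")
    if np.any(np.diff(times) < 0):
        raise KineticsError("requested times must be non-decreasing")
    out: list[StateFractions] = []
    state = c0
    t_phase_start = 0.0
    phase_idx = 0
    phases = protocol.phases
    for t in times:
        # advance whole phases that end before t
        while (
            phase_idx < len(phases) - 1
            and t_phase_start + phases[phase_idx].duration <= t
        ):
            state = _propagate_phase(
                model, state, phases[phase_idx], phases[phase_idx].duration
            )
            t_phase_start += phases[phase_idx].duration
            phase_idx += 1
        out.append(_propagate_phase(model, state, phases[phase_idx], t - t_phase_start))
    return out
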