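# Methods

`photoxs` estimates the wavelength-dependent photoconversion cross-sections
σ_k^λ (m² mol⁻¹) and quantum yields Φ_k of a photoreceptor that interconverts
between an inactive state P_I and an active state P_A, from time-resolved
absorption spectra measured under defined illumination protocols.  This note
records the model, the estimation procedure, the numerical choices, and what
the synthetic test beds do and do not demonstrate.

## Forward model

**Photochemistry.**  Under a light source with spectral photon fluence z^λ
(µmol m⁻² s⁻¹ per 1-nm bin), the population-level transition rates are

    k_I = Σ_λ σ_I^λ z^λ · 10⁻⁶     (activation,   P_I → P_A)
    k_A = Σ_λ σ_A^λ z^λ · 10⁻⁶     (deactivation, P_A → P_I)

The 10⁻⁶ converts µmol photons to mol photons so rates land in s⁻¹.  With
σ ≈ 10⁴ m² mol⁻¹ and 11 µmol m⁻² s⁻¹ illumination this gives k ≈ 0.11 s⁻¹ —
switching saturating within minutes, as observed for slow in-vitro phytochrome
fragments; cross-sections around 10⁵ m² mol⁻¹ give the seconds-scale switching
typical of full-length plant phytochromes in vivo.  Sums (not integrals) over
a common 1-nm grid are used throughout; channels on different grids are
linearly interpolated onto the light's grid.

**Thermal reversion.**  P_A relaxes to P_I in darkness.  Populations whose
dark decay needs n > 1 exponentials are modelled as *static pools*: a fraction
α_j of molecules shares σ and Φ but reverts with its own β_j, and pools do not
exchange molecules.  This reproduces the multi-exponential dark decay
Σ_j α_j e^(−β_j t) exactly.  The alternative — dynamic exchange between
sub-states — is not modelled; the data types used here cannot distinguish the
two, and the pool picture keeps every light phase analytically solvable.

**Monomer propagation** is closed-form per pool:
a_j(t) = a_j^∞ + (a_j(0) − a_j^∞) e^(−(k_I+k_A+β_j) t) with
a_j^∞ = k_I/(k_I+k_A+β_j).

**Dimers.**  A dimer carries n_c = 2 chromophores; species II, AI, AA.
Assuming independent protomers, activation proceeds II→AI at 2k_I and AI→AA at
k_I, deactivation AA→AI at 2k_A and AI→II at k_A, and thermal reversion AA→AI
at 2β_AA, AI→II at β_AI, with distinct homo-/hetero-dimer rates.  Phases are
integrated exactly with the matrix exponential of this 3-state generator; the
photostationary state follows from detailed balance of the birth–death chain.
The aggregate active fraction is c_A = p_AI + 2p_AA ∈ [0, 2] and
c_A + c_I = n_c is conserved by construction.  The aggregate dark decay
relaxes with eigenvalues 2β_AA and β_AI; when a fitted two-exponential decay
is fed into a dimer analysis, the faster mode is assigned to the homo-dimer
(an identifiability convention — amplitudes alone cannot distinguish the
assignment).

**Absorbance** (the measurement model):

    A(λ, t) = 2.303 · l · c_tot · Σ_k c^k(t) · ε_k^λ,    ε_k = σ_k / Φ_k

with path length l in cm (default 1.06, a path-corrected 1-cm cuvette) and
total photoreceptor concentration c_tot in mol L⁻¹ (default 0.34 mg/ml of a
70 kDa protein).  The scaled spectra ε̂ = 2.303·l·c_tot·ε appear only as
transient views, never stored, to avoid double-scaling bugs.

## Estimation procedure

**Step 1 — thermal reversion.**  From a dark series (saturating activating
light, then darkness), the normalised decay
E(t) = (A(λ,t) − A(λ,∞)) / (A(λ,0) − A(λ,∞)) is wavelength-independent and is
averaged over the 5 bins of largest |A(0) − A(∞)| (best signal-to-noise;
configurable).  E(t) is fitted by Σ α_j e^(−β_j t) with Σ α_j = 1 enforced by
parameterisation (for n = 2: free α₁ ∈ [0,1]), β₁ ≥ β₂ to break
label-switching, 20 log-uniform multi-starts for β over [10⁻⁷, 1] s⁻¹, and
bounded trust-region least squares.  Both n = 1 and n = 2 fits are reported
with AICc; the choice of order is left to the user, mirroring standard
practice of judging the decay shape directly.  Strictly, the decay amplitudes
are the *light-off active weights* α_j a_j(0)/Σ α_j a_j(0); they equal α_j
when photoconversion is much faster than reversion during the preparatory
illumination, which holds for all shipped presets.

**Step 2 — search space.**  Two saturated spectra (after prolonged activating
and after prolonged inactivating light) span an affine family containing the
scaled pure-state spectra:

    ε̂_I^λ = A_act^λ + X₁ (A_inact^λ − A_act^λ),
    ε̂_A^λ = A_act^λ + X₂ (A_inact^λ − A_act^λ).

The scalars (X₁, X₂) are fixed by self-consistency: computing σ = ε·Φ from the
candidate spectra and the photostationary fractions c_act, c_inact under each
saturating light (including reversion), the saturated conditions must map onto
themselves:

    X₁ + (X₂ − X₁) c_act = 0,      X₁ + (X₂ − X₁) c_inact = 1.

These equations are implicit in (X₁, X₂).  They are solved by damped
fixed-point iteration (damping 0.5, tolerance 10⁻⁹ on both residuals, budget
500 iterations, divergence guard at |X| > 10⁸) with a 2-D Powell-hybrid root
fallback.  When a population can be driven pure (non-overlapping bands, β = 0)
the solution is (X₁, X₂) = (1, 0) and the saturated spectra *are* the scaled
pure-state spectra.  For dimers the pure-state spectra sit at affine
coordinates c_A = 0 and c_A = n_c, so the X₂-combination above generalises to
the family value at X₁ + (X₂ − X₁)·n_c; the monomer formula is the n_c = 1
case.

Candidate spectra at off-optimal Φ can have negative lobes; for kinetics (and
the S-sums below) they are clipped at zero, since negative cross-sections are
unphysical.  At the optimum of noiseless data no clipping occurs.

The quantum-yield *ratio* R = Φ_A/Φ_I follows from the photostationary balance
under the activating light.  With S_k = Σ_λ ε_k^λ z_act^λ · 10⁻⁶:

    R° = (S_I/S_A) · (−n_c (X₂ − X₁)/X₁ − 1)        (monomers: −(X₂/X₁)(S_I/S_A))
    R  = R° − (β_eff/Φ_I) / S_A

The subtracted term is positive whenever β_eff > 0, so R ≤ R°: the
reversion-free ratio bounds the true one.  For multi-pool or dimer systems
β_eff is the single rate that reproduces the aggregate photostationary active
fraction, β_eff = k_I/f − (k_I + k_A) with f = c_A/n_c computed numerically
from the full stationary state; this makes the bound relation exact for the
aggregate system (it reduces to β for one pool).

Tabulating the solve over a log-uniform grid of (Φ_A, Φ_I) ∈ [10⁻³, 1]²
(default 50×50; each cell warm-started from its left neighbour, the cell
above, or the pure-state solution, which keeps the convergence set stable
under refinement) yields the search space; R^max = max over convergent cells
of positive R° is the optimiser's upper bound for R.  Non-convergent cells
are recorded; more than 50 % failing aborts the build.

**Step 3 — fit.**  The decision variables are (Φ_A, R) ∈ [0,1] × [0, R^max],
exactly the box the bound construction provides.  For each candidate:
Φ_I = Φ_A/R; solve (X₁, X₂); form ε and σ = ε·Φ; simulate both measurement
directions; score

    χ² = Σ_series Σ_t Σ_λ ((D(t,λ) − S(t,λ)) / ν_t^λ)²

on difference spectra D(t,λ) = A(λ,t) − A(λ,0) (simulated minus its own t = 0
likewise), with ν the per-point measurement error (ν = 1 for noiseless
synthetic data; points with ν = 0 get unit weight — they carry no noise and no
mismatch).  Because the affine family pins the saturated endpoints to the data
by construction, only the *transient* time points discriminate between
candidates — which is why the difference-spectrum cost is the right objective.
A failed implicit solve contributes a large finite penalty (10¹²) rather than
an exception, and Φ_I > 1 is penalised the same way, so multi-start
exploration survives pathological corners.

Minimisation is bounded Nelder-Mead (fatol 10⁻¹², xatol 10⁻⁹) from 100 seeded
random starts by default; the derivative-free simplex tolerates the ~10⁻⁴
numerical noise the inner implicit solve leaves on the cost surface, which
finite-difference gradients do not.  Because R^max can sit orders of magnitude
above plausible ratios, start draws alternate uniform and log-uniform in R
(Φ_A always uniform); purely uniform draws would concentrate all starts at
implausibly large R where the cost surface is nearly flat.  The best endpoint
is reported along with every start's endpoint for basin diagnostics.  Runs are
deterministic given a seed.

**Profile likelihoods.**  For Φ_A, Φ_I or R, the profiled χ² re-optimises the
remaining free parameter at each grid value (bounded scalar minimisation over
a local bracket plus the full box).  The 95 % CI is the connected region
around the optimum with Δχ² ≤ χ²(0.95, 1) = 3.8415; an interval edge on the
scan boundary is flagged one-sided.  The default scan spans ±50 % of the
optimum with 101 points; studies that need guaranteed-wide scans should pass
an explicit grid.

**Classical baseline.**  The two-condition (Butler-style) estimator unmixes
the saturated spectra under *assumed* saturated active fractions (default
(1, 0)), then extracts Φ from the observed mono-exponential approach rates to
photoequilibrium via k_obs = Φ_I S_I + Φ_A S_A + β under each light (a 2×2
linear solve).  The assumed fractions are explicit inputs because that
assumption is exactly what fails for overlapping bands — the package's
estimator exists to replace it.  The historical literature contains several
variants of this analysis; this implementation is the standard linear-unmixing
one with the assumption exposed, which suffices for exact/biased behaviour on
the pure/overlapping presets respectively.

## Synthetic test beds

No laboratory spectra ship with the package; `photoxs.synthgen` generates
every input.  Shared design: 1-nm grid 400–800 nm, Gaussian LED sources
(FWHM 20 nm, total fluence 11 µmol m⁻² s⁻¹), Gaussian cross-section bands,
c_tot = 0.34 mg/ml / 70 kDa, l = 1.06 cm, and per series a t = 0 spectrum,
n_t = 5 measurement points, and a saturation spectrum.  Measurement times are
log-ish spaced over ~3 time constants of the relevant process.  Presets:

| preset | bands (act/inact) | Φ_A, Φ_I | reversion | structure | noise |
|---|---|---|---|---|---|
| redgreen | 660/550 nm, non-overlapping, peak 10⁴ | 0.1, 0.34 | none | monomer | — |
| overlap680 | 660/680 nm, heavy overlap, peak 10⁴ | 0.1, 0.3 | none | monomer | — |
| dual_reversion | 660/730 nm, red overlap, peak 3·10⁵ | 0.1, 0.17 | 70 %: 5·10⁻³, 30 %: 5·10⁻⁴ s⁻¹ | monomer | — |
| dimer | same | 0.1, 0.17 | β_AA 5·10⁻³, β_AI 5·10⁻⁴ s⁻¹ | dimer | — |
| noisy_rf | same | 0.1, 0.2 | 5·10⁻³ s⁻¹ | monomer | 10 % CV |

Noise is multiplicative Gaussian, A → A(1 + cv·ξ), applied independently per
point with a seeded generator, and the error estimate ν = cv·|A| is attached
to the series — the relative-error model a spectrophotometer user would
assume.

What the generator does *not* emulate: wavelength-dependent baselines and
drift, scattering, photobleaching, chromophore maturation, instrument
band-pass, or correlated noise.  Passing tests therefore demonstrate the
estimator's correctness under its own measurement model, not robustness to
instrument systematics; the validation stage of the pipeline (residual report
against held-out series) is the intended guard when applying the method to
real data.

## Problem sizes and defaults

The shipped studies and tests run at deliberately modest sizes chosen as the
smallest that leave comfortable safety margins on every recovery: search-space
grids of 10–20 points per Φ axis (production default 50), 12–20 optimisation
starts (default 100), profile scans of 21–31 points, and a 25-replicate
coverage study on a 5-nm-subsampled 550–800 nm window.  Recoveries on the
noiseless presets are exact to ≈10⁻⁸, far inside the 10⁻³ margins asserted,
so grid and start counts are not the binding factor.

## Known limitations

- Two photoactive states only; photocycle intermediates (e.g. Lumi-R) and
  N-state cycles are out of scope.
- Pool semantics for multi-exponential reversion are a modelling convention
  (see above); light-phase behaviour of real sub-populations may differ.
- The dimer transition stoichiometry assumes independent protomers
  (factor-of-2 combinatorics) and distinct homo-/hetero-dimer reversion.
- β is temperature-independent; no photobleaching.
- Profile CIs assume the stated per-point errors; with misspecified ν the
  3.8415 threshold loses its 95 % calibration.
- More fundamentally, the profile intervals treat the t = 0 and saturation
  spectra — which anchor the extinction-coefficient family and the difference
  spectra — as exact.  When those anchors are themselves noisy, the
  estimator's replicate-to-replicate spread is dominated by anchor noise that
  the χ² curvature does not see, and the intervals become sharply
  anti-conservative (the coverage study in the test suite measures this
  directly).  Averaging repeated scans of the anchor spectra, or error
  propagation through the affine family, would be needed for calibrated
  intervals on fully noisy data.
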