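# Methods

## Model

The package implements the smallest microscopic binding scheme that can
exhibit cooperativity: a macromolecule M with two ligand-binding sites and
four microscopic states (both sites empty; site 1 occupied; site 2
occupied; both occupied), connected by eight mass-action rate coefficients.
Concentrations are in μM, time in s, association coefficients in μM⁻¹s⁻¹,
dissociation coefficients in s⁻¹. The five coupled rate equations for
[M⁰⁰], [L₁M¹⁰], [L₁M⁰¹], [L₂M¹¹] and free [L] conserve total macromolecule
and total ligand exactly.

Detailed balance (thermodynamic cycle closure) requires the two paths from
the empty to the doubly occupied state to give the same overall equilibrium
constant; `RateConstants` enforces this at construction (relative tolerance
1e-6) unless explicitly overridden for nonequilibrium exploration, in which
case the closed-form equilibrium oracles no longer apply.

Two standard parameterizations generate all built-in scenarios:

- *cooperative*: k₁ = k₂ = K_o·k_off, k₁₍₂₎ = k₂₍₁₎ = ω·K_o·k_off, all
  dissociation coefficients k_off (default 1 s⁻¹). The intrinsic constant
  of an empty site is K_o and the second binding event is ω-fold faster.
- *two different sites*: site i has kon = K_oi·k_off independent of the
  other site's occupancy.

## Time-course integration

Fixed-step classic 4th-order Runge–Kutta (numba-compiled). The default
step is 0.01 divided by the fastest total rate scale,
max(k_on)·max([L]₀, [M]₀) + max(k_off); a negative-concentration excursion
beyond −10⁻⁹ of the concentration scale triggers an automatic halving
retry (up to 8 times) before raising. RK4 preserves the two linear
conservation laws to near machine precision; the test suite checks ≤ 10⁻⁹
relative at every recorded step.

**Convergence.** Equilibrium is declared when the relative concentration
change of every species stays below the threshold (default 10⁻⁵, i.e.
10⁻³ %) over a trailing window of 10 consecutive check intervals. The
check interval is auto-scaled to the slowest kinetic timescale,
1/(min k_off + min k_on · max([L]₀ − 2[M]₀, 0)) — a conservative lower
bound on the slowest relaxation rate. A single-step criterion at a fixed
cadence would either trigger while the slow mode still carries ~10⁻⁴ μM of
amplitude or make high-ligand runs (where relaxation is thousands of times
faster) prohibitively long; the windowed rule leaves the returned
equilibrium state with residual derivatives below 10⁻⁶ μM/s in the
scenarios used here. Runs that hit `max_time` (default 400 slowest-rate
periods) are flagged `converged=False`, never silently accepted, and
isotherm assembly refuses them by name.

`detect_equilibrium` applies the same windowed rule to a recorded course
and returns the earliest state at which it is established (a constant
course returns its first state).

## Isotherms and ligand grids

One time course per total-ligand concentration; each contributes its
equilibrium (free [L], ⟨n⟩) pair. Default grids are log-spaced at 25
points per decade spanning two orders of magnitude below and above the
relevant dissociation constant(s) — for cooperative sweeps both 1/K_o and
1/(ωK_o), since for ω far from 1 the two binding steps saturate decades
apart. A linear-grid option exists for even concentration steps, but the
log grid is the default everywhere: linear steps leave too few points in
the low-concentration part of the transition region for a meaningful Hill
analysis. Sweep grids additionally compensate each total for the ligand
expected to be bound at equilibrium, so that tight binders
(K_o·[M]₀ ≫ 1) still reach saturating *free* ligand despite depletion.
The named scenarios use their fixed declared ranges (0.01–100, 0.01–300,
0.01–6, 0.01–3·10⁵ μM) with [M]₀ = 1 μM.

Closed-form equilibrium models are implemented through their binding
polynomials: Z = 1 + 2K_oL + ωK_o²L² (cooperative),
Z = 1 + (K_o1+K_o2)L + K_o1K_o2L² (two different sites), Z = 1 + K_oL
(single site), plus the phenomenological Hill curve
θ = KL^nH/(1+KL^nH). Simulated equilibria match these to better than
10⁻³ in ⟨n⟩ (tested), which is the package's internal consistency check
between the kinetic and thermodynamic descriptions.

The **characteristic free-ligand span** L(θ=0.9)/L(θ=0.1) is computed by
root bracketing on the closed forms, or by monotone PCHIP interpolation in
(ln L, θ) for tabulated isotherms. It is 81 for any single class of sites,
smaller under positive and larger under negative cooperativity.

## Hill analysis

`estimate_site_number` estimates the apparent plateau N by linear
extrapolation of ⟨n⟩ against 1/[L] over the last five isotherm points,
unrounded — a blind analysis reports what the data supports, which under
strong negative cooperativity is ≈ 1.06 apparent sites for a two-site
molecule. The isotherm must have roughly plateaued (last three points
within 5%); otherwise the function asks for a wider ligand range rather
than guessing.

`wyman_hill_plot` computes y = ln(⟨n⟩/(N−⟨n⟩)) against x = ln[L], drops
unusable points (⟨n⟩ ≤ 0 or ≥ N), and marks the transition region as
fractional saturation ∈ [0.1, 0.9] — the same band that defines the span
statistic. `hill_coefficient` least-squares fits a cubic y(x) to the
transition points (in centred coordinates for conditioning) and evaluates
its derivative over the transition x-interval only: the interior critical
point if it lies inside, otherwise the boundary values. Extrapolating the
cubic beyond the fitted range is meaningless, so the extremum search is
confined to the data. The reported n_H is the
extremum deviating most from 1 (maximum for positive, minimum for negative
cooperativity); an exact tie reports 1.

Accuracy against the analytic midsaturation slope 2/(1+ω^(−1/2)): within
0.3% for ω ≥ 2, within ~3% down to ω ≈ 0.2, but biased high by ~6% at
ω = 0.1 and ~9% at ω = 0.05 — the broad double transition of strong
negative cooperativity is genuinely beyond a cubic. The bias is a property
of the procedure (verified on exact closed-form isotherms, not a
simulation artifact); consequently the fitted n_H crosses 0.5 near
ω ≈ 0.07 rather than at the analytic ω = 1/9·… ≈ 0.1 boundary. For the
truncated hidden-site isotherm (ω = 0.02, ligand ≤ 6 μM) the same effect
bounds the fitted n_H away from exactly 1: the pointwise Hill slope dips
to ~0.95 mid-region and rises above 1 where the hidden site begins to
fill, so the cubic's bounded extremum lands at ≈ 1.06 for any defensible
plateau estimate. "Looks like a single site" is accurate to about ±0.06
in n_H, not better.

## Free energies and equivalence

ΔG°assoc = −RT ln(K·c_std) with a 1 μM standard state, so association
constants in μM⁻¹ enter the logarithm directly; ΔG°int = −RT ln ω.
Temperature defaults to 298.15 K (not dictated by the model; the ±11.4
kJ/mol interaction-energy range of the ω ∈ [0.01, 100] sweep corresponds
to RT ln 100 at this temperature) and is configurable.

The equivalence mapping K_o1,2 = K_o(1 ± √(1−ω)) and its inverse
K_o = (K_o1+K_o2)/2, ω = K_o1K_o2/K_o² are exact algebra; ω > 1 raises an
error (complex roots — positive cooperativity has no two-different-sites
counterpart), and the inverse always yields ω ≤ 1 by AM–GM.

## Kinetic discrimination and fitting

`paired_timecourses` builds the matched pair (all dissociation
coefficients equal, default 1 s⁻¹; association coefficients from the exact
mapping), integrates both models with a shared step and recording grid per
ligand concentration, and returns Δ⟨n⟩(t) traces with their extremum. For
the canonical pair (K_o = 0.55 μM⁻¹, ω = 0.33058 vs K_o1 = 1,
K_o2 = 0.1 μM⁻¹) the equilibrium isotherms agree to ~10⁻⁶ while Δ⟨n⟩
peaks at 0.027–0.17 for [L]₀ between 5 and 300 μM, the peak coming earlier
and larger at higher ligand — equilibrium cannot discriminate the models,
kinetics can.

Isotherm and time-course fits use lmfit (Levenberg–Marquardt) with
positivity bounds and Jacobian standard errors. Kinetic fits impose the
two macroscopic association constants from the equilibrium stage by
reparameterization: the association coefficients are derived from the
constraints and the free dissociation scales (two per model), so the
constraints hold exactly at every iteration instead of approximately via
penalties. Model selection uses AICc (with the Gaussian-likelihood form
n·ln(RSS/n) + 2k + correction, k counting the noise variance); an
extra-sum-of-squares F-test is available for nested comparisons.
Single-trace phase classification fits one- and two-exponential rise
models and returns "2" only when the F-test favors the second phase at
α = 0.01; traces that dip more than 10% of their amplitude below their
running maximum are rejected as non-monotone rather than misclassified.

## Synthetic data

The simulations themselves are noise-free and deterministic. For fitting
and recovery experiments `add_noise` injects seeded, homoscedastic
additive Gaussian noise on ⟨n⟩ (default experiments use σ = 0.01–0.02,
the scale of a careful titration). This emulates measurement error only:
no baseline drift, no heteroscedasticity, no concentration errors, and no
instrument response function. Recovery results (ω within 15% from noisy
isotherms; the generating kinetic model selected in ≥ 90% of replicates
from four time courses at σ = 0.01) therefore characterize the
identifiability of the models under idealized error, not the difficulty of
any particular experimental technique. The discrimination power check uses
time courses at [L]₀ = 5–50 μM sampled log-uniformly to 8 s — informative
pre-equilibrium conditions; a single low-concentration trace leaves the
models statistically tied (ΔAICc < 2), matching the caveat that
discrimination depends on where the data are taken.

## Numerical choices and degenerate inputs

- Step size, check cadence and `max_time` are auto-scaled per condition as
  above; all can be overridden through `SimulationConfig`.
- Convergence threshold 10⁻⁵ per check interval; threshold 0 is
  unattainable by construction (strict inequality) and detection then
  errors explicitly.
- [L]₀ = 0 integrates to a constant course and yields the isotherm point
  (0, 0).
- Isotherm points with microscopic non-monotonicity from simulation
  round-off are monotonized by a cumulative maximum before validation
  (effect ≤ 10⁻⁹).
- Cubic fits use centred x for conditioning; fits with fewer than five
  transition points are refused.
- Fit parameters use lower bounds only; wide two-sided bounds degrade
  MINPACK's internal scaling.

## Problem sizes

Default scenario runs integrate 70–190 time courses per isotherm (25
grid points per decade), which keeps every end-to-end workflow in the
seconds range and the full test suite under a minute on one CPU after
numba's one-off compilation. Denser grids change the reported Hill
coefficients only in the fourth decimal.

## Known limitations

- Exactly two binding sites; no oligomeric or >2-site schemes, no MWC/KNF
  mechanistic models.
- Deterministic mass action only (no stochastic simulation); concentrations
  are continuous averages.
- Fixed-step RK4 is the method of record here; it is robust for these
  systems but not a general stiff-ODE solver.
- The cubic-fit Hill coefficient inherits the procedural bias quantified
  above for ω ≲ 0.2; use the closed-form midsaturation slope when the
  model, rather than the data-analysis procedure, is of interest.
- The two-exponential classifier assumes monotone association traces under
  (approximately) constant free ligand.
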