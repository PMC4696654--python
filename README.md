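# coopbind

Phenomenological modeling of cooperative ligand binding to a macromolecule
with two binding sites: deterministic mass-action simulation of the
microscopic binding scheme, equilibrium isotherms assembled from time
courses, Wyman Hill-plot analysis, free-energy calculations, and kinetic
discrimination of binding models that equilibrium measurements cannot tell
apart.

## The problem

A macromolecule M with two ligand-binding sites populates four microscopic
states — M⁰⁰ (empty), L₁M¹⁰, L₁M⁰¹ (singly occupied), L₂M¹¹ (doubly
occupied) — connected by eight rate coefficients (k₁, k₂, k₁₍₂₎, k₂₍₁₎ for
association, μM⁻¹s⁻¹; k₋₁, k₋₂, k₋₁₍₂₎, k₋₂₍₁₎ for dissociation, s⁻¹).
The intrinsic association constant of an empty site is K_o = k₁/k₋₁, and
the **cooperativity factor** ω multiplies the intrinsic constant for the
second binding event: ω = 1 means independent sites, ω > 1 positive and
ω < 1 negative cooperativity, with interaction free energy
ΔG°int = −RT ln ω.

`coopbind` integrates the five mass-action rate equations with a fixed-step
classic 4th-order Runge–Kutta scheme until the relative concentration
change of every species falls below 10⁻³ % over a trailing window,
harvests the equilibrium binding density

  ⟨n⟩ = ([L₁M] + 2[L₂M]) / [M]ₒ = ([L]ₒ − [L]) / [M]ₒ

across a grid of total-ligand concentrations, and analyzes the resulting
isotherm the way an experimenter would:

- **Hill coefficient** n_H = extremum of ∂ln(⟨n⟩/(N−⟨n⟩))/∂ln[L], from a
  third-order polynomial fitted to the Hill plot's transition region
  (fractional saturation 0.1–0.9), with the site number N read off the
  isotherm plateau. For two identical interacting sites the midsaturation
  slope is 2/(1 + ω^(−1/2)).
- **Equivalence mapping**: identical sites with negative cooperativity
  (K_o, ω ≤ 1) and two different independent sites (K_o1, K_o2) give the
  same binding polynomial when K_o1 + K_o2 = 2K_o and K_o1·K_o2 = ωK_o²;
  the roots K_o1,2 = K_o(1 ± √(1−ω)) are complex for ω > 1.
- **Kinetic discrimination**: the equivalent models differ *before*
  equilibrium; `paired_timecourses` quantifies Δ⟨n⟩(t), and `fit_kinetics`
  fits both kinetic models to ⟨n⟩(t) data under exact macroscopic
  equilibrium constraints so AICc (or an F-test) can select one.
- **Hidden sites**: with strong negative cooperativity (e.g. ω = 0.02) the
  isotherm saturates near ⟨n⟩ = 1 with an apparent affinity close to 2K_o
  (statistical effect); the second site only shows up at very high ligand
  concentration, in equilibrium and in the kinetics (bi-exponential time
  courses).

## Worked example

```python
import coopbind as cb

# two identical sites, K_o = 1 uM^-1, omega = 10, M_total = 1 uM
iso = cb.preset_isotherm("fig3")          # simulate 101 time courses
res = cb.analyze_isotherm(iso)            # Wyman plot + cubic fit
print(f"n_H = {res.n_h:.3f} ({res.operator})")

sp = cb.free_ligand_span(cb.IdenticalIndependent(1.0, 2))
print(f"span = {sp.ratio:.1f} ({sp.log10_span:.3f} log units)")

k_o, omega = cb.equivalent_cooperative(1.0, 0.1)
print(f"equivalent cooperative model: K_o = {k_o}, omega = {omega:.5f}")
```

prints

```
n_H = 1.517 (max)
span = 81.0 (1.908 log units)
equivalent cooperative model: K_o = 0.55, omega = 0.33058
```

The Hill coefficient 1.517 sits a few percent above the analytic
midsaturation slope 2/(1+10^(−1/2)) ≈ 1.519 — the cubic fit restricted to
the transition region carries a small, known bias. The 81-fold span of a
single site class is the baseline against which cooperativity is judged,
and the equivalence mapping shows that two sites with constants 1 and
0.1 μM⁻¹ are thermodynamically indistinguishable from identical sites with
K_o = 0.55 μM⁻¹ and ω ≈ 0.331.

The same workflows are scriptable from the shell:

```bash
coopbind isotherm --preset fig3 -o fig3_iso.csv
coopbind hill --isotherm fig3_iso.csv
coopbind equivalence --ko1 1 --ko2 0.1
coopbind discriminate --ko 0.55 --omega 0.33058 --l-grid 5,10,25 -o disc
coopbind preset-run --id fig7a -o out/
```

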