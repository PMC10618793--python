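# Methods

## Scope and data model

The package analyses plate-based SPR screens of small molecules against an
immobilized receptor. The unit of kinetic analysis is a *cycle set*: all
injection cycles for one analyte — an ascending concentration series on the
active flow cell, matched reference-cell cycles on identical time grids,
and zero-concentration blank cycles. Each cycle is stored on its own clock
(t = 0 at cycle start) with explicit association/dissociation phase
boundaries; on disk, cycles live in a TSV dialect with a categorical
`phase` column, written with shortest round-tripping float formatting so
that write→read is bit-exact.

## Preprocessing

Double referencing follows standard practice: (1) reference-cell
subtraction, (2) DMSO solvent correction, (3) subtraction of the mean of
the blank cycles, blanks being processed identically first. The order of
(2) and (3) is a convention of this package; the two commute exactly for
the additive artifact model used by the generator.

Solvent correction is calibrated from eight DMSO-only cycle pairs spanning
a 2.5–3.8 % DMSO design. The excluded-volume mismatch (active − reference
plateau) is fitted as a polynomial of the reference plateau (degree 2 by
default; plateaus are the median of the final 20 % of the association
window). The correction applied to a sample is interpolated linearly in
cycle index between the two calibration sets bracketing it — the simplest
defensible model of drift between periodic calibrations. Evaluation
outside the calibrated reference-response span is flagged rather than
refused.

## Kinetic fitting

The 1:1 Langmuir model is fitted globally: one (kon, koff, Rmax) shared by
all cycles of a set, minimizing summed squared residuals over the
association and dissociation windows. Numerical choices:

- **Parameterization/bounds.** Fitting is in log10-parameter space —
  rates are scale parameters and log-space makes the problem
  well-conditioned — with bounds kon ∈ [1e2, 1e9] 1/(M·s),
  koff ∈ [1e-5, 1] 1/s, Rmax up to 10× the theoretical value when known.
- **Initialization** is deterministic: koff from a log-linear regression of
  the dissociation tail at the highest concentration, K_D and Rmax from a
  steady-state (isotherm) prefit of the per-cycle plateaus, kon = koff/K_D.
  No random restarts are needed; fits are exactly reproducible.
- **Convergence** uses scipy's trust-region reflective solver with
  ftol = xtol = gtol = 1e-12; noise-free synthetic series are recovered to
  better than 1e-6 relative error.
- **Standard errors** come from the Jacobian at the optimum
  (σ² (JᵀJ)⁻¹ with σ² = SSR/dof), delta-transformed from log space.

Steady-state (affinity) analysis fits `Req(C) = C·Rmax/(C + K_D)` to
plateau responses at ≥3 concentrations and flags series whose maximum
concentration stays below K_D/10 (saturation never approached).

The theoretical saturation response is the mass-ratio scaling
`Rmax = (MW_analyte/MW_ligand)·RU_immobilized·stoichiometry`. The ligand
(receptor construct) molecular weight is an explicit input; it is not
published for the motivating dataset, so the package never assumes one.

### QC flags

- `not_detectable`: no cycle's plateau response exceeds
  max(3 × noise sd, 0.1 RU). The noise sd is estimated robustly from first
  differences of each trace (MAD/√2). The comparison deliberately uses the
  *plateau* (median of the last 20 % of the association window), not the
  per-sample maximum: the maximum of thousands of noise samples exceeds
  3 sd with near certainty, which would misclassify every true non-binder.
  The 0.1 RU absolute floor represents instrument resolution and catches
  degenerate noise-free traces.
- `matrix_binding`: any observed response exceeds the theoretical Rmax —
  the signature of non-specific accumulation in the sensor matrix.
- `slow_dissociation`: the highest-concentration cycle retains > 50 % of
  its peak at the end of the dissociation window. The 50 % retention
  threshold is configurable and was chosen so that any off-rate slow
  enough to leave most of the complex bound after a 420 s dissociation
  (koff ≲ 1.6e-3 1/s) is flagged.
- `at_bound`: a fitted rate lies on (or within one standard error of) a
  box bound — the fit is not uniquely determined.

Per-compound failures in a screen degrade to `n.d.` report rows with a
logged reason; rows are never dropped.

## Competition analysis

For analytes A and B sharing one site, the equilibrium occupancies are
computed in the ratio form `FO_A = (C_A/K_DA)/(1 + C_A/K_DA + C_B/K_DB)`,
algebraically identical to the reciprocal form but regular at zero
concentration (FO → 0 as C → 0, the documented limit convention). The
competitive prediction is `FO_A·Rmax_A + FO_B·Rmax_B`; the non-competitive
prediction is the exact sum of the single-analyte responses. Rmax values
are explicit inputs — fitted or theoretical — and never inferred silently.

The decision rule formalizes "the measured combined response resembles one
prediction": with distances d_c and d_n from the measured combined RU to
the two predictions, the verdict is competitive when d_c < d_n·(1 − m),
non-competitive when d_n < d_c·(1 − m), else inconclusive; the relative
margin m defaults to 0.1. This reproduces all published verdicts for the
motivating panel (antagonist pair non-competitive; CBD and CBV competitive
with the 5-BDBD probe).

Mixture concentrations are interpreted as *per-component* concentrations
(each analyte at the stated final concentration), the convention under
which the published occupancy examples reproduce.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the instrument's full physics:

- **Design**: 8 concentrations spanning 0.4–300 μM (geometric, ≈2.6-fold —
  the closest even ladder to a 3-fold series with both endpoints),
  180 s association / 420 s dissociation at 1 Hz, two blanks, matched
  reference cycles.
- **Signal**: the closed-form 1:1 model; **artifacts**: linear drift, an
  association-phase bulk refractive-index shift common to both flow cells,
  and i.i.d. Gaussian noise (default sd 0.5 RU, a realistic short-term
  noise figure for screening-grade data). Identical (spec, seed) pairs are
  bit-identical.
- **Competition mechanisms**: `competitive_shared_site` integrates the
  two-analyte occupancy ODE (dθ_A/dt = kon_A·C_A·(1 − θ_A − θ_B) −
  koff_A·θ_A, LSODA, rtol 1e-10) — deliberately independent of the
  closed-form occupancy expressions so the two can serve as mutual
  oracles; `noncompetitive_independent_sites` realizes the additive null
  generatively. Combined responses are read at the ODE steady state
  (30 dissociation time constants), single responses from single-site
  occupancies; noise-free non-competitive experiments are exactly
  additive and competitive ones strictly sub-additive.
- **Panels**: binder K_D log-uniform over 1e-6–3.4e-4 M (the published
  screen envelope), koff log-uniform over 0.05–0.5 1/s (typical of
  small-molecule screens and keeping kon inside its fit bounds), Rmax
  uniform over the 158–205 RU theoretical span; non-binders are
  noise-only traces. A truth table accompanies every panel.

What the generator does *not* emulate: mass-transport limitation,
rebinding, surface heterogeneity, regeneration scarring, or correlated
(1/f) noise. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to every artifact of
real instrument data.

## Problem sizes in the shipped checks

The simulation studies run at the study design itself (8-cycle series,
600 samples/cycle): parameter recovery uses 20 independent noisy screens,
mechanism recovery 200 simulated competition experiments — sizes at which
the medians and proportions tested are stable across seeds.

## Known limitations

- Only the 1:1 model is implemented (no two-state, bivalent or
  mass-transport models); compounds whose traces need those models will
  fit poorly and typically carry QC flags instead.
- The solvent-correction and read-out conventions (plateau medians for
  fitting and calibration; a single-sample report point 5 s before
  injection end available via `report_point_response`) are project
  choices; vendor software may differ in detail.
- Published theoretical competitive RU values for the motivating panel
  cannot be recomputed exactly because the Rmax values used in them are
  not published; the occupancy machinery is instead certified against the
  dynamical oracle, and published verdicts are reproduced from the
  published RU values directly.
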