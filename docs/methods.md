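# Methods

## Model

`brainpbpk` implements a minimal physiologically-based pharmacokinetic
(mPBPK) model of monoclonal-antibody disposition with mechanistic brain
detail. The model has 16 ordinary differential equations: 13 molar antibody
concentrations — plasma, lumped tissue (vascular / endosomal unbound /
endosomal FcRn-bound / interstitial), brain vascular, BBB endosome
(unbound / bound), brain ISF, BCSFB endosome (unbound / bound), CSF, and
lymph — plus 3 free-FcRn concentrations, one per endosomal space.

Transport processes, written as amount fluxes (L/h × M) divided by the
receiving compartment volume:

* **Convection.** Plasma perfuses the lumped tissue at Q_T and the brain at
  Q_B; venous return is reduced by the lymph flows (Q − L). Vascular escape
  is paracellular/convective, scaled by one minus a reflection coefficient:
  L_T·(1−σ_Tv) into tissue interstitium, Q_B_ECF·(1−σ_BBB) across the BBB
  into ISF, Q_B_CSF·(1−σ_BCSFB) across the BCSFB into CSF. With the default
  σ_BBB = 1 the paracellular BBB route is exactly closed.
* **FcRn recycling.** Pinocytotic uptake into each endosomal space is
  symmetric from the luminal and abluminal sides at the uptake clearance
  (CLUP_T for tissue; CLUP_BBB / CLUP_BCSFB in brain, split from CLUP_B in
  proportion to barrier surface area, f_BBB = SA_BBB/(SA_BBB+SA_BCSFB)).
  Unbound endosomal antibody binds free FcRn (kon, koff) or is degraded at
  k_deg; the bound complex is exported at the uptake-clearance rate, a
  fraction FR (FR_B in brain) returning to the vascular side and (1−FR)
  delivered across the barrier. FcRn returns to the free pool on export, so
  free + bound FcRn is conserved exactly in each endosome.
* **Brain fluid turnover.** ISF drains to CSF by bulk ECF flow Q_B_ECF, and
  ISF and CSF are additionally cleared glymphatically to lymph at
  Q_B_ECF·(1−σ_ISF) and Q_B_CSF·(1−σ_CSF). The ISF compartment carries both
  the full bulk outflow to CSF and the glymphatic outflow simultaneously —
  the literal reading of the flux description; this is a modeling choice
  that slightly shortens the ISF residence time relative to a merged-flow
  reading. Lymph returns to plasma at L_T + L_B.

Lysosomal degradation of unbound endosomal antibody is the only elimination
route: the total-drug balance d/dt Σ V_i·C_i = −k_deg·(V_Te·C_Te,u +
V_BE,BBB·C_BBB,u + V_BE,BCSFB·C_BCSFB,u) holds identically and is enforced
by property tests, as is FcRn conservation.

Doses are IV boluses added directly to the plasma compartment:
C_P += dose·BW/MW/V_P with dose in mg/kg, body weight BW in kg, antibody
molecular weight MW in g/mol (default 150 kDa, a typical IgG; the drug's
identity enters only through MW and the FcRn kinetic constants).

## Parameters

The packaged table carries one column per species (mouse, rat, monkey,
human), stored exactly as printed at 3 significant figures: volumes (L),
plasma/lymph/bulk flows (L/h), FcRn kinetics, uptake rate constants (1/h),
reflection coefficients, and barrier surface areas (m²). Secondary
transport parameters are always recomputed, never read: CLUP_T = k_CLUP_T·V_Te,
CLUP_B = k_CLUP_B·(V_BE,BBB + V_BE,BCSFB), the f_BBB split, L_T = 0.002·Q_T
and L_B = Q_B_ECF + Q_B_CSF. `validate_consistency` checks the derivations
against the printed values at a 1.5% relative tolerance — the rounding
level of a 3-significant-figure table; all four species pass with a worst
deviation below 0.5%.

The human tissue plasma-flow entry is taken as 160.5 L/h, the value under
which the lymph-flow relation reproduces the printed L_T = 0.321 L/h
exactly. Default body weights are 70 kg (human — the reference sensitivity
subject), 0.028 / 0.25 / 6.2 kg for mouse / rat / monkey (conventional
laboratory values, configurable; only the human value is fixed by the
reference design).

The `reduction` module implements the generic organ-lumping recipe (volume
sums per sub-space, the four-ventricle CSF sum, Q_T = Q_lung − Q_brain,
L_T = 0.002·Q_T, the vascular-volume-weighted σ_Tv, L_B = Q_B_ECF + Q_B_CSF)
so minimal parameters can be regenerated from any organ-level table. An
empirical lymph-flow proportionality constant used by older platform models
is deliberately absent: lymph flows come only from the two relations above.
Reproducing the packaged σ_Tv values would require the parent model's organ
volumes, which are not shipped; the module is validated by conservation
properties and scale checks instead.

## Numerics

Default solver: LSODA with rtol 1e-10, atol 1e-16 and the analytic
Jacobian (the system is linear except for the three bilinear FcRn-binding
terms, so the Jacobian is a constant matrix plus six state-dependent
entries per endosome). A high-fidelity preset (`SolverConfig.reference()`:
BDF, rtol 2.3e-14, atol 1e-22) mirrors the reference MATLAB ode15s
configuration; on this system the two agree in plasma to better than 1e-6
relative. Halving the default tolerances moves the plasma AUC by far less
than 0.01%, and a fixed-step RK4 integration at dt = 1e-4 h agrees with the
stiff solution to < 0.1% over 10 h.

Output is interpolated onto a uniform grid (0.01 h step for
concentration-profile studies, 1 h for sensitivity; both configurable), and
AUC is the trapezoid rule on that grid, so the exposure metric reflects the
reported trajectory exactly. Integration restarts at each dose event with
the bolus added to plasma; the post-dose value is reported at a coinciding
grid point. Output concentrations in (−1e-12, 0) M are clipped to zero
(solver undershoot at atol scale); anything more negative raises an
integration-quality error rather than being silently repaired. A 17th
bookkeeping state can accumulate the degraded amount so tests audit mass
balance (dose = Σ amounts + degraded, < 0.1% at every output time).

## Sensitivity analysis

The one-at-a-time design multiplies a single parameter per run by a
lognormal draw (log-scale mean 0, sd 0.25), recomputes all derived
parameters, re-simulates (human, 70 kg, 10 mg/kg, 1000 h, 1 h step) and
records S = (AUC_perturbed/AUC_base − 1)·100% for plasma, ISF and CSF AUC.
The default set is 27 parameters × 1000 samples; every parameter owns an
RNG stream keyed by (master seed, parameter name), so extending the
parameter list never shifts existing draws. Failed perturbed runs are
warned about and excluded from summaries, never silently dropped.

Two design choices deserve explanation:

* **Clamping.** Fraction-valued parameters (the σ's, FR, FR_B) are clamped
  to [0, 1] after multiplication. σ_BBB sits at 1, so an unclamped upward
  draw would mean a negative reflection coefficient complement — a
  convective flux *out of* ISF proportional to the vascular concentration,
  which drives ISF negative; similarly FR > 1 would route a negative
  fraction across the barrier. Clamping keeps every perturbed model
  physically admissible at the cost of making upward σ_BBB draws null
  perturbations.
* **Rank metric.** Parameters are ranked by mean |S|. The signed median of
  S is reported but deliberately not used for ranking: under a symmetric
  multiplier design the median multiplier tends to 1, so the signed median
  of S tends to 0 for *every* parameter as n grows, and for a clamped
  boundary parameter (σ_BBB) any median-based statistic sits exactly at the
  unstable 50th-percentile boundary between the null upward half and the
  explosive downward half. Mean |S| — the expected absolute percentage
  change in exposure — is stable across seeds and captures one-sided heavy
  responses. Under it the converged rank order is: σ_BBB ≫ all others for
  ISF, σ_BCSFB ≫ all others for CSF, and V_Te first, σ_Tv second for
  plasma, with V_L and other bulk transit parameters below 1%.

At 100 samples per parameter the plasma ranks 2–4 (σ_Tv, FcRn_total,
k_deg, mean |S| within ~1 percentage point of each other) are not reliably
separated; the test suite therefore asserts the three top-1 ranks exactly
and σ_Tv's membership in the plasma top 3 at that scale, with the strict
second place verified at the converged 1000-sample design.

## Problem sizes used by tests and the acceptance script

Conservation and proportionality checks run the human 10 mg/kg simulation
over the full 1000 h horizon at 0.5–1 h output steps; the sensitivity rank
check runs 27 × 100 = 2700 simulations (the scaled design that already
separates the dominant parameters); the fixed-step oracle uses 1e5 RK4
steps over 10 h. These sizes were chosen as the smallest at which each
claim is cleanly decided.

## Limitations

* The full 100-ODE whole-body parent model is not reimplemented; exposure
  ratios against it require an externally supplied reference trajectory
  (CSV harness provided). Synthetic references used in tests are labelled
  as such and only validate the harness arithmetic.
* No target engagement, no endogenous IgG competition for FcRn, no
  subcutaneous/oral routes, and no molecular-size-dependent permeability:
  the drug enters only through MW and FcRn kinetics, so an affinity
  improvement always predicts a longer half-life.
* The single CSF compartment lumps the ventricles and subarachnoid space;
  comparisons against multi-compartment CSF references must choose which
  reference series to map it to.
* Synthetic fixtures (jittered parameter sets, toy organ tables,
  mono-exponential trajectories) exercise code paths and conservation
  laws; passing them says nothing about predictive accuracy in real
  animals, which rests on the physiological parameter table itself.
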