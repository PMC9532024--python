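# Methods

`collateralflow` simulates steady-state cerebral blood flow and pressure on
a network of compliant vessel segments, with three scientific goals: (i)
quantify how leptomeningeal collaterals sustain perfusion when a major
cerebral artery is occluded, (ii) model a permeable thrombus as a porous
(Darcy) segment and map its permeability and length onto pressure drop,
residual flow and infarct volume, and (iii) invert dynamic-CTA-style
thrombus measurements (transit time, void fraction, clot length, lumen
area) into an effective clot permeability.

## Flow model

Blood is incompressible and flow is steady (heartbeat-averaged).  On the
discretized network (every vessel carries at least three nodes with grid
spacing ≤ 2.5 mm) the nodal pressures satisfy Kirchhoff mass balance

    Σ_j G_ij (P_i − P_j) = Q_i,

with segment conductance G = π r⁴ / (2 (ζ + 2) μ L).  ζ parameterizes the
velocity profile: ζ = 2 is the parabolic Poiseuille profile, the default
ζ = 9 a blunt profile appropriate for these vessels.  Dynamic viscosity
defaults to μ = 3.5 mPa·s (the table that states it prints only "mPa"; we
read it as mPa·s, the standard value).

Vessels are elastic tubes with a linear pressure–area (here radius) law

    P = P₀ + E h / (r₀² (1 − ν²)) · (r − r₀),

with Poisson ratio ν = 0.5, Young's modulus E = 1.6 MPa for all cerebral
vessels, reference pressure P₀ = diastolic (80 mmHg default), and wall
thickness from the empirical human fit
h = r₀ (0.2802 e^(−0.5053 r₀) + 0.1324 e^(−0.01114 r₀)) (r₀ in mm).  The
corresponding distensibility (dA/dP)/A = 2 (1 − ν²) r₀² / (r E h) is of
order 10⁻⁶ Pa⁻¹ at the 0.2 mm pial radius, matching clinical values.

The linear system is solved by sparse direct LU factorization; pressures
and radii are iterated as a fixed point (conductances from the previous
radii, radii from the new pressures) until the maximum componentwise
relative pressure change falls below 10⁻⁶.  The termination norm is the
max relative component; the source text does not name the norm, so it is
configurable.  Radius updates are under-relaxed (factor 0.7 by default;
the converged answer is relaxation-independent, which the tests check) and
after convergence a few unrelaxed polish iterations drive the (P, r) pair
onto the pressure–area law to machine precision.

### Boundary conditions

The heart node carries the inlet flow Q_in = 100 ml/s as a source term;
every outlet is a lumped resistance to a pinned venous pressure
p_out = 666 Pa.  Before any autoregulation, all outlet resistances are
scaled by one common factor until the simulated inlet pressure equals
p_in = 12 500 Pa to 10⁻⁶ relative (a monotone scalar root-find; the flow
condition holds identically under the source formulation).  This
calibration runs once, on the healthy network only.

### Autoregulation

Each pial outlet adjusts its resistance toward a constant-flow set point
q = Q_brain / N_total (Q_brain = 12.5 ml/s), clamped to
[P_low/q, P_upp/q] with P_low = 10 mmHg (maximal dilation) and
P_upp = 100 mmHg (maximal constriction).  All outlets are updated
synchronously from one solved pressure field (clamping applied at update
time); the loop stops when the ∞-norm relative change of the resistance
vector and the unclamped-outlet flow deviation are both below 10⁻⁶.  A
damping factor (default 1, falling back to 0.5 if the residual stalls)
stabilizes the iteration without moving the fixed point.  Stroke runs
start from the healthy calibrated resistances and re-autoregulate; the
inlet calibration is not repeated.

## Thrombus

A clot of length L and permeability κ in a host vessel of lumen area
A = π r₀² contributes a Darcy resistance R_thrombus = μ L / (κ A).  The
total resistance of the vessel segment containing the thrombus is
R_T = R_thrombus + R_vessel, where R_vessel is the viscous resistance of
the whole host vessel; the host's conductance is replaced by 1/R_T
(distributed over its discretized elements by length) and the clot span is
rigid — Darcy's law replaces the velocity-profile assumption inside it.
Taking R_vessel over the whole host (rather than only the clot span) makes
pressure drop and flow exact functions of R_T: any (κ, L) pair with equal
R_T produces an identical system, the collapse the sweep tests verify.
κ = 0 is implemented as exact conductance removal (segment deletion), not
a large finite resistance, avoiding conditioning artifacts; nodes isolated
by the removal are pinned to p_out.

Infarct volume uses a static perfusion threshold: an outlet is infarcted
when its fractional flow-rate change ΔQ = (Q_healthy − Q_stroke)/Q_healthy
reaches 0.4 — i.e. at most 60% of its healthy flow remains — and
IV = V_brain · N_infarcted / N_total with V_brain = 1390 ml.  Ties are
counted as infarcted (the threshold is stated as a 40%-or-more drop).  The
healthy baseline is recomputed for every network realization; outlets are
paired by identity, never across seeds.  This is a penumbra-style
criterion, not a mechanistic tissue-death model.

## Synthetic vasculature

The patient-specific brain mesh and vascular atlases behind the original
model are not distributable, so the generator builds a desk-scale
surrogate whose *topology* matches the modelled physiology:

* **Systemic tree** — a small fixed table (heart → aorta →
  carotids/vertebrals → circle-of-Willis branches) with
  literature-typical radii and lengths, explicitly a surrogate and
  user-overridable; a rest-of-body outlet on the descending aorta absorbs
  the non-cerebral cardiac output.  The boundary calibration makes the
  absolute systemic resistances non-critical.
* **Pial network** — the dual graph of a geodesic-sphere triangulation
  (sphere volume = V_brain), 3-regular away from territory seams, every
  vessel at the 0.2 mm pial reference radius with its geometric edge
  length.  Perfusion territories are fixed angular sectors: six cerebral
  (left/right × anterior/middle/posterior), a cerebellar band (~15% of the
  surface) and a brainstem cap (~5%), sized so that no territory's lumped
  feeding trunk starves its outlets in the healthy state.
* **Collaterals** — the territory-crossing pial edges.  The collateral
  score is the probability with which each crossing edge is independently
  retained (absent/poor/moderate/good ↔ 0.05/0.25/0.50/0.65, the
  full-scale calibration of the source study, kept as labels here).
* **Feeding trees** — one Murray-law bifurcating tree per territory,
  built by recursive spatial bisection of the territory's pial nodes with
  split fraction equal to the subset-size fraction, so every pial node is
  reached by exactly one leaf and daughter radii satisfy
  r_parent³ = r_i³ + r_j³ exactly at every junction.  Tree segment length
  is 10 × radius (the length–radius ratio).  Letting leaf radii emerge
  from Murray's law rather than fixing them at 0.2 mm is essential at desk
  scale: with ~10²–10³ outlets instead of ~10⁵, per-outlet flow is 30–300×
  larger, and a fixed 0.2 mm leaf would place the entire microvascular
  pressure drop inside the trees and clamp every outlet at maximal
  dilation in a healthy brain.
* **Outlets** — one penetrating-artery stub (0.2 mm radius, 2.5 mm
  cortical length) per pial node; its end node is a model outlet.  The
  "penetrating artery density 1 mm⁻¹" of the source parameter table has
  undefined units, so outlet count is controlled directly through the
  surface resolution (20 · 4^k triangles at refinement k; the default
  k = 3 gives N_total = 1280).

All randomness (collateral selection, optional tree jitter, synthetic
cohorts) flows from explicit integer seeds; identical configuration and
seed give byte-identical network tables.

### What desk scale does and does not establish

The surrogate reproduces the model's mechanisms — boundary calibration,
autoregulation set point and clamps, Darcy dose-response, the collapse
onto R_T, collateral rescue of the occluded territory (at refinement ≥ 3
the mean infarct volume falls steeply with collateral score) — but not the
full-scale numbers: published mean infarct volumes per grade
(280.5/136.0/51.7/35.8 ml), the 309 ml maximal right-MCA volume, cohort
median pressure drops (65.1–75.3 mmHg) and the measured-cohort
permeability range all depend on the 113 913-outlet patient mesh and the
unpublished 44-patient measurement table.  They are shipped as
reference-only constants.  At refinement 2 and below, crossing pial edges
are so few and long that collaterals cannot rescue any outlet past the
infarct threshold: the infarct volume is flat in the collateral score
there, which is a resolution artifact, not model behaviour.

## Measurement inversion

For a patient with transit time Δt, void fraction ε, clot length L and
contralateral lumen area A_MCA, the flow through the occluded segment is
Q = ε A_MCA L / Δt.  Per collateral grade, a response curve Q_thrombus(R_T)
is tabulated by forward simulation over a resistance grid spanning ≥ 4
decades (default 10³–10¹⁰ Pa s/ml, 13 points, averaged over 5 network
seeds), interpolated monotonically (PCHIP in log R_T) and inverted by
bisection; the pressure drop and infarct volume are read from the same
simulations at the inverted resistance.  The permeability follows from the
algebraic inverse κ = μ L / (A (R_T − R_vessel)).  ε = 0 (or a flow below
the curve's occluding branch) routes to the fully-occluding simulation;
flows above the healthy branch are clamped to it with a per-patient
warning rather than failing the cohort.  A non-monotone tabulation beyond
noise tolerance is an error.

The synthetic cohort generator stands in for the clinical table, sampling
log-uniform Δt ∈ [1, 30] s, uniform ε ∈ [0, 0.5], L ∈ [3, 28] mm (the
clinically observed clot-length range) and A_MCA ∈ [3, 8] mm².

## Numerical choices and limitations

* Internal unit system is strict SI; mm, mmHg and ml appear only at the
  interfaces (1 mmHg = 133.322 Pa).
* Pinned-boundary solves eliminate the pinned unknowns exactly
  (free/pinned partition) before the sparse LU; a connected component
  without any pressure constraint is reported as a structured error.
* Tree termination ties (leaf radius exactly at the terminal radius)
  terminate, with a 10⁻¹² relative tolerance against floating-point drift.
* The critical resistance above which a clot dominates the downstream
  microcirculation is reported in Pa s/ml; no threshold is hard-coded
  (the source discussion's value has an ambiguous unit).
* Out of scope: pulsatile/wave haemodynamics, thrombolysis transport,
  mechanistic infarct formation, non-Newtonian rheology, circle-of-Willis
  variants, image-derived patient anatomy.
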