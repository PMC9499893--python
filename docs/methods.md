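# Methods

## Model

`thromboflow` solves the transport of three species — activated platelets
φ_a, non-activated platelets φ_n (both number concentrations, m⁻³) and ADP
(molar concentration, mol m⁻³) — on a *frozen* velocity field. The one-way
coupling is the central modelling assumption: the presence of activated
platelets does not alter the flow (no momentum sink for a growing clot), so
the flow can be solved once and the species equations integrated on top of
it with time steps limited only by the species dynamics, not by the flow.
The AP field is a risk *surrogate*: it marks where activated platelets
accumulate, not where a clot mechanically forms.

Activation is a one-way conversion φ_n → φ_a with two additive cues. The
mechanical rate is a power law in the scalar shear stress τ,

    A_M(φ_f, τ) = (1 − φ_f) C^{1/β} β φ_f^{(β−1)/β} τ^{α/β},

whose constants are empirical and calibrated for τ in Pa and A_M in s⁻¹.
Note that A_M multiplies the *total* platelet count (φ_a + φ_n) in the
source term — already-activated platelets contribute to the conversion flux.
The formula is implemented exactly as written, with two guards: φ_f is
clamped to [0, 1] when within 1e-9 of the bounds before exponentiation
(violations beyond that raise the model-collapse error instead of being
silently clipped), and cells with no platelets at all return zero sources.
The exponent (β−1)/β must be positive for the law to be regular at φ_f = 0;
parameter sets violating this are rejected.

The chemical rate is a threshold switch, A_C = ADP/(ADP_t·t_ADP) once ADP
reaches ADP_t and zero below — a deliberately crude stand-in for
dose-response kinetics whose discontinuity at the threshold (a jump to
1/t_ADP) is the model's known weak point. The ADP balance is tied to the
platelet balance exactly: S_ADP = R_ADP·S_a, with R_ADP the ADP released by
one activation.

The stress stimulus τ = √J₂ (second invariant of the deviatoric stress
tensor; pure shear s gives τ = s) is evaluated at cell centers from
cell-centered velocity gradients — second-order central differences inside,
first-order one-sided at boundaries. Two tensor definitions are available:
viscous-only (the default/baseline) and the total tensor with the Boussinesq
Reynolds-stress closure, (μ+μ_t)(∂u_i/∂x_j+∂u_j/∂x_i) − ⅔ρk δ_ij. Because
τ is a deviatoric invariant, the isotropic −⅔ρk term cannot change it; for
uniform μ, μ_t on an incompressible field the Reynolds-augmented τ is
exactly (1 + μ_t/μ) times the viscous one. The asserted test suite leans on
this identity.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| D_a, D_n | platelet diffusivities | 1.58e-11 | m² s⁻¹ |
| D_ADP | ADP diffusivity | 1e-20 | m² s⁻¹ |
| R_ADP | ADP released per activation | 3e-17 | mol |
| ADP_t | chemical activation threshold | 2e-3 | mol m⁻³ |
| t_ADP | chemical characteristic time | 1 | s |
| C, α, β | power-law constants | 1.4854e-7, 1.4854, 1.4401 | — |
| φ_a0, φ_b0 | background AP / NP levels | 25e12, 475e12 | m⁻³ |
| ρ | blood density | 1056.4 | kg m⁻³ |
| μ | dynamic viscosity (per-cell input) | 3.5e-3 | Pa s |
| dt | transport step | 1 | s |

D_ADP = 1e-20 m² s⁻¹ is honored literally: ADP is effectively
advection-only. Viscosity is a per-cell input with a constant default; when
a non-Newtonian flow solution supplies a local apparent viscosity, the caller
passes it per cell. The near-identical printed values of C and α are taken at
face value from their empirical source.

Solver controls: stabilization tolerance 1e-6 relative change per step,
sustained over 5 consecutive steps (both configurable); iteration cap 500;
reaction sub-step limiter 10% relative change per sub-step with a budget of
100 sub-steps per window.

## Discretization

The grid is uniform, cell-centered, 0-based (i, j) with x rightward and y
upward; 2D fields are embedded in the 3D stress formulas with w = 0 and all
z-derivatives zero. The transport operator is assembled in conservative flux
form: first-order upwind convection (chosen for boundedness; higher-order
schemes are out of scope) and second-order central diffusion. On a closed
domain the operator's column sums vanish, so the cell-volume integral of
each species is conserved to solver precision — the basis of the
conservation acceptance check.

Boundary conditions per domain side: `wall` (zero total flux), `inlet`
(fixed species value; the background platelet pool at φ_a0/φ_b0 enters
continuously, ADP enters at 0 — these inlet levels are this package's
choice, as species boundary conditions are generally not reported with the
model) and `outlet` (advective outflow at the upwind cell value, zero
diffusive flux). Species fields start uniform at the background values.

Time integration is backward Euler for transport (one sparse LU per species,
factorized once per operator and time-step size, reused across steps).
The reaction contribution for each 1 s window is integrated first, per cell,
by the explicit sub-stepped kinetics integrator, and the resulting increment
is added to the right-hand side of the implicit solve:

    (I − dt·A) φ^{n+1} = φ^n + dt·b + Δ_react(φ^n).

This form was chosen deliberately over Lie splitting (transport solve, then
reaction applied to the result). Splitting leaves an O(dt·A·S) bias in the
fixed point, which at the convective CFL numbers the 1 s step implies
(hundreds) inflates steady AP increments by orders of magnitude. With the
source in the RHS, the fixed point satisfies A φ + b + Δ_react(φ)/dt = 0,
so the steady state coincides with that of the exact semi-discrete system up
to the sub-integration of the source; a dt = 1 s run and an explicit
dt = 1e-3 s reference agree on per-region steady AP to machine precision in
the test problems.

The sub-step limiter sizes explicit reaction sub-steps so no species changes
by more than 10% per sub-step; the relative rate watched includes the ADP
growth rate measured against max(ADP, ADP_t/2), because the chemical rate is
linear in ADP and its growth must be resolved where it feeds back. When the
sub-step budget is exhausted the remainder of the window is taken in one
uncapped step; genuinely stiff sources then push the activated fraction out
of [0, 1] and raise `ModelCollapseError` — reproducing the physical failure
mode of an explicit source treatment (observed when the chemical threshold is
lowered to 1e-4 mol m⁻³ at t_ADP = 1 s, and circumvented at t_ADP = 100 s)
rather than silently corrupting the state. Negative concentrations from
round-off are floored at zero with a diagnostic count; systematic negativity
(beyond 1e-6 of the background) also aborts as collapse.

Termination mirrors the stabilization criterion of the parent approach: the
relative change of every region's volume-averaged φ_a must stay at or below
the tolerance for the configured number of consecutive steps. Whether the
criterion must hold for one step or several is exposed as configuration.

## Synthetic flows

The generator replaces pump CFD output with desk-scale divergence-free
fields covering the regimes that matter to the activation model: Couette
(uniform τ), plane Poiseuille (linear τ profile, zero at the centerline) and
a channel with an embedded recirculation cell standing in for the stator-wake
regions where activated platelets accumulate. The vortex is the curl of a
compactly supported streamfunction bump ψ = A sin(πξ) sin(πη) inside a
sub-rectangle, evaluated as a *discrete* curl on the same centered stencil
the divergence check uses — so the composite field is exactly
divergence-free in the discrete sense, not merely to truncation error. The
sub-rectangle must keep a two-cell margin from the domain boundary (the
default box is clamped to it); the discrete curl has support one cell beyond
the box.

Two preconfigured demo cases exist:

* `demo_channel` — 5 cm × 1 cm at 0.5 m/s peak: wall stresses of a few Pa,
  a strong recirculation cell, convenient for transport/kinetics testing;
* `demo_gap_channel` — 2 mm × 0.2 mm at 3 m/s peak: a pump bearing/blade
  clearance analog with shear rates of order 1e4–1e5 s⁻¹ and τ up to
  ~1000 Pa. Differentiating the power law shows the β-sensitivity carries a
  −ln(C)/β² ≈ 10.9 term while the α-sensitivity is ln(τ)/β, so α dominates a
  ±10% perturbation study only where τ exceeds roughly 150 Pa — clearance-gap
  conditions, which is also where devices actually activate platelets. The
  sensitivity analyses therefore run on this case.
* `closed_recirculation` — the demo channel with the through-flow turned
  off: a pure vortex with zero velocity through every boundary, usable with
  all-wall boundaries as a conservation testbed. (Blocking a through-flow
  profile with walls instead piles species up against the blocked outflow —
  a tortured configuration that says nothing about conservation and
  eventually trips the chemical threshold.)

What the synthetic fields do *not* emulate: 3D geometry, turbulence (μ_t and
k fields are smooth imposed overlays, not a closure), rotating frames,
non-Newtonian viscosity variation, and the sharp wall layers of a real pump.
Passing tests on these fields validate the transport/kinetics machinery and
the directional trends of the model — not a quantitative device prediction.

Region masks for the demos are four equal axial bands named Region1–4, by
analogy with the upstream-to-downstream compartments of an axial pump
(inflow straightener, fore bearing, impeller passage, outlet stator). The
naming is a convention only and makes no geometric claim.

## Analysis conventions

Scaled AP is the per-mille increase over the background level,
1000·(φ_a − φ_a0)/φ_a0; it can be negative where φ_a dips below background.
Region aggregation is the volume-weighted mean (a plain mean on the uniform
grid). The clinical-comparison statistics are ordinary least squares of
observed thrombus frequencies on per-region scaled AP (R² = 1 − SS_res/SS_tot
with the constant-response convention R² = 0; two-sided slope p from the t
distribution, n−2 dof) and Pearson's χ² of thrombus counts against the
uniform-by-chance null.

The sensitivity sweep perturbs α, β, C by fractional amounts (±10% by
default, α additionally ±20%), the background activated fraction at 1, 5,
10, 20% of the fixed total pool (5e14 m⁻³), the stress mode (viscous vs
Reynolds-augmented) and optionally ADP_t/t_ADP. Percent deviations are
signed, relative to the unperturbed run of the same case; magnitudes are
used for ranking. Collapsed runs are recorded as failed rows and the sweep
continues. Operating-point analogs are two scalar knobs on the demo field —
a stress-magnitude multiplier (speed analog) and a carrier-velocity
multiplier at fixed τ (flow analog); they are analogs, not reproductions of
an rpm / flow-rate map.

## Problem sizes

The shipped tests and the acceptance script use 64×32 cells for the
conservation run (1000 steps, ~1 s wall time), 48×24 for the gap-channel
sensitivity battery and 24×12 for the fine-time-step equivalence reference
(40 000 explicit steps) — sizes at which every check runs in seconds while
all asserted properties are grid-converged in direction.

## Known limitations

* The chemical switch is discontinuous; a saturating (Hill-type) response is
  the natural refinement and is out of scope here.
* First-order upwinding is diffusive; steep AP fronts are smeared, and the
  per-region averages inherit a first-order grid dependence.
* The activated fraction enters the mechanical law with already-activated
  platelets contributing to the conversion flux; this is kept exactly as the
  model defines it and not reinterpreted.
* One-way coupling means no clot growth, no flow obstruction, no surface
  chemistry; AP concentration ranks regions, it does not predict thrombus
  mass or timing.
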