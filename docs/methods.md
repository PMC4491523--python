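# Methods

`pulsereduce` simulates pulse waves in branched networks of compliant
vessels with the nonlinear one-dimensional (1D) equations of blood flow,
and reduces such networks by lumping peripheral branches into windkessel
(0D) models that preserve the network's net resistance and total
compliance. This note records the model, the numerical choices, the
synthetic-data generator and the limits of what the tests demonstrate.

## 1D model

Each arterial segment is an impermeable, axisymmetric elastic tube with
axial coordinate `x ∈ [0, l]`. Conservation of mass and momentum for the
cross-sectional area `A(x,t)`, mean axial velocity `U(x,t)` and pressure
`P(x,t)` read

    ∂A/∂t + ∂(AU)/∂x = 0
    ∂U/∂t + U ∂U/∂x = −(1/ρ) ∂P/∂x + f/(ρA),

with blood density `ρ` and wall friction per unit length
`f = −2(ξ+2)πμU`, where `μ` is the blood viscosity and `ξ` the polynomial
order of the velocity profile (`ξ = 2` is Poiseuille flow, the default
`ξ = 9` near-plug flow typical of large arteries). The system is closed
by the elastic tube law

    P = P_d + (β/A_d)(√A − √A_d),

where `A_d(x)` is the cross-section at the diastolic pressure `P_d` and
`β(x) = (4/3)√π E h` collects the wall's elastic modulus and thickness.
The local pulse wave velocity (PWV) is

    c = √(β/(2ρA_d)) · A^{1/4},

so `β = 2ρ c_d² √A_d` when a segment is specified by its diastolic PWV.
Segments taper linearly in diastolic radius and in `β`. The
characteristic impedance `Z₀ = ρc/A_d` is the local ratio of pressure to
flow for a forward wave; terminal `R1` values equal to the outlet `Z₀`
minimise terminal reflections.

Boundary conditions: a prescribed periodic volumetric inflow at the root
(a reflective flow source — backward waves alter pressure, never the
imposed flow), conservation of mass plus continuity of total pressure
`P + ρU²/2` at junctions (energy losses neglected; n-furcations are
allowed although anatomical networks are binary), and a three-element
windkessel (proximal resistance `R1`, compliance `C`, distal resistance
`R2`, outflow pressure `p̂_out`) at every terminal vessel.

### Parameter accounting

Each 1D segment carries three independent parameters (length, diastolic
area, diastolic PWV); each terminal adds two (peripheral resistance and
compliance — `R1` is tied to `Z₀`); six global items remain (ρ, μ, ξ,
`P_d`, the inflow waveform, the shared `p̂_out`). The encoded reference
trees reproduce the published totals: 227 parameters for the 55-segment
tree, 91 for its 21-segment first-generation reduction, 271 for the
67-segment tree with both hands, 171 for the 37-segment variant.

## Numerical scheme

The solver is a second-order MUSCL finite-volume scheme on `(A, U)` with
fluxes `(AU, U²/2 + P/ρ)`, local Lax–Friedrichs (Rusanov) numerical
fluxes and two-stage SSP Runge–Kutta time stepping. Design points:

- **Well-balancing.** Slopes are reconstructed in *pressure* and
  velocity (monotonised-central limiter, one-sided at segment-edge
  cells) and converted to area with the interface diastolic properties.
  The constant-pressure rest state is then an exact discrete equilibrium
  even on tapered vessels (verified to ~1e-13 relative drift per cycle).
- **Boundaries and junctions** couple through the Riemann invariants
  `W± = U ± 4(c − c_d)` of the tube-law system. Junction states solve
  mass conservation + total-pressure continuity by a damped Newton
  iteration (tolerance 1e-10, at most 50 iterations), batched over all
  junctions with equal child counts.
- **Terminals** integrate the windkessel capacitor pressure `p_c`
  (`p = p_c + R1 q`, `C dp_c/dt = q − (p_c − p̂_out)/R2`) alongside the
  1D state; terminals whose `R2·C` is below 2.5 time steps are treated
  as quasi-steady resistive outlets `R1 + R2`, which covers the exact
  `C → 0` limit without a stiffness restriction.
- **Time step**: fixed, chosen from the diastolic wave speeds with a
  1.6× margin for systolic stiffening at the requested CFL number
  (default 0.5), and re-checked against the instantaneous CFL condition
  every step.
- **Initial conditions and periodicity.** The classical cold start is
  `(A, U, P) = (A₀(x), 0, 0)`; `SolverSettings.initial_pressure` allows
  warm starts at an estimated mean pressure, which shortens the
  transient governed by the RC time constant of the periphery without
  changing the periodic state. Cycles repeat until the cycle-to-cycle
  max relative change of probe pressures falls below the periodicity
  tolerance (default 1e-3; budget 20 cycles, a non-converged run is
  flagged and warned, never silently accepted). The final cycle is
  resampled to 1024 uniform points by monotone cubic interpolation.

Measured behaviour on smooth pulses: convergence order ≈ 1.6 (limiter
clipping keeps it below 2), < 1% peak decay per transit at 100 cells per
pulse width, reflection < 1e-5 from admittance-matched junctions, and
per-cycle volume-balance error at the level of the periodicity residual
(the discrete scheme conserves volume exactly; the residual measures
distance from periodicity).

## Model reduction

A terminal vessel plus its `R1–C–R2` windkessel is replaced by a
two-element windkessel

    R_new = R2 + R1 + R_v
    C_new = (C_v R2 + C_v R1 + C R2 + R_v C_v)/(R2 + R1 + R_v),

with the vessel's own resistance and compliance obtained from axial
profile integrals evaluated by adaptive Gauss–Kronrod quadrature
(relative tolerance 1e-12; `K3` is sharply weighted toward the narrow
end of tapered vessels):

    R_v = 2(ξ+2)πμ·K3,  K3 = ∫ A_d⁻² dx
    C_v = K1/ρ,         K1 = ∫ A_d/c_d² dx.

The derivation linearises the 1D equations about the diastolic state,
space-averages them (mean-value theorem), neglects the fluid-inertia
term `ρK2 dq/dt` (`K2 = ∫ A_d⁻¹ dx` is computed as a diagnostic only)
and assumes the vessel transit time `∫dx/c_d` is small against the
cardiac period. `reduction_validity` reports the transit-time ratio
(flagged above 0.1) and the inertance-to-resistance time-scale ratio
`ρK2/(R_total T)`.

Sibling lumps merge in parallel into a three-element windkessel on their
parent: resistances combine harmonically, compliances add, and the
proximal resistance is set to the parent's outlet `Z₀` to minimise
reflections. When the parent's `Z₀` exceeds the combined peripheral
resistance (a degenerate case outside the derivation) `R1` is clamped to
99% of the total with a warning, preserving the net resistance.
Terminals merged at one junction must share a single outflow pressure; a
mismatch is an error rather than a silently averaged value. Two
schedules compose these primitives: generation trimming (lump the
deepest generation of bifurcations onto its parents) and peripheral
pair lumping (collapse the leaves at one junction). Both preserve the
net resistance exactly (checked against an independent nodal-circuit
solve to 1e-10 on random trees) and the total effective compliance, and
the final `(R, C)` of a full reduction is independent of the order in
which independent subtrees are processed.

The *generation* of a segment increments at every bifurcation except
along the designated trunk (the aorta), whose segments stay at
generation 0 — so a five-generation tree trims 55 → 53 segments at the
first step (only the two deepest arm vessels are lumped) and reaches the
21-segment aorta-plus-first-generation model after four steps.

### Validity regime of the dynamic equivalence

The neglected term in the lumping derivation is `C(R1+R_v)·dq_out/dt`.
The lumped branch therefore reproduces the distributed (inertia-free)
dynamics only when *both* the transit-time ratio is small *and* the
forcing is slow compared with `C(R1+R_v)` and `R2·C`. The acceptance
check drives a 3 mm-radius branch with a half-sinusoid spanning the
whole period (the slow-forcing regime) and compares against a
200-compartment linearized RC-chain: the max relative pressure error is
≈ 0.4% at transit ratio 0.02 and grows monotonically to ≈ 3% at 0.3.
With pulsatile systolic ejections and peripheral `C(R1+R_v)` of the
order of the systolic rise time, a *single* lumped branch shows much
larger high-frequency mismatch — it is the recursive application within
a compliant tree, where peripheral flows are already smoothed, that
makes the method accurate at the waveform level.

## Hypertensive transformation

`apply_hypertension(network, factor)` multiplies every diastolic PWV by
`factor` (i.e. `β → factor²β` at fixed `A_d`) and every terminal total
resistance `R1+R2` by `factor`, resetting `R1` to the new outlet `Z₀`;
compliances and outflow pressures are unchanged (whether peripheral
compliance should also change is physiologically open; we keep it
fixed). With `factor = 1.5` the representative tree roughly doubles its
pulse pressure at a ~40% higher mean — and its reduced models are *more*
faithful than the normotensive ones (e.g. 0.6% vs 1.2% average
aortic-root pressure error for the 21-segment model), because higher
PWVs shorten transit times and stiffer vessels weaken the neglected
inertial term.

## Error metrics

Complete (C) and reduced (R) waveforms are compared on a shared uniform
grid of N_t = 1024 points (a choice, not an external constant; the
average metrics are insensitive to refinement) by six scalars: unsigned
average relative errors in pressure and flow and signed
systolic/diastolic errors, with all flow errors normalised by
`max_j Q_j^C` to avoid division by near-zero diastolic flows. No
time-shift correction is applied; waveforms are compared at identical
phases. The offset-noninvariance of the flow normalisation is
documented behaviour.

## Synthetic networks

No measured arterial data ships with the package. `fixtures.make_tree`
builds networks whose *topology* follows the anatomy of the larger
systemic arteries (10 aortic segments; brachiocephalic, carotid,
subclavian/arm, coeliac, mesenteric, renal, iliac/leg branches; optional
hands with two superficial palmar-arch halves and four digital arteries
each) but whose geometric and elastic values are representative draws
from physiological ranges: radius 1–15 mm, length 2–50 cm, diastolic
PWV 4–12 m/s, with peripheral vessels shorter, narrower and stiffer than
central ones so that deepest-generation transit-time ratios stay below
0.1 by construction. Terminal windkessels take `R1 = Z₀` at the outlet;
`R2` values are distributed by outlet area and rescaled by a scalar
root-solve so the fully reduced tree has a declared net resistance
(default 1.4e8 Pa·s/m³ ≈ 1.05 mmHg·s/mL), and terminal compliances are
rescaled by an affine solve to a declared total effective compliance
(default 1e-8 m³/Pa ≈ 1.33 mL/mmHg, diastolic time constant ≈ 1.4 s).
With the default 70 mL, 60 bpm half-sinusoid ejection this produces
central pressures in the physiological range. A fixed seed makes every
fixture bit-reproducible; an optional jitter perturbs geometry by ±5%
for ensemble runs.

The 37-segment tree deserves a note: its published parameter total (171)
forces 37 segments with 27 terminals, i.e. only 10 internal segments —
which no tree containing both the full aorta *and* an internal right-arm
chain can satisfy. We pin the counts and encode the variant as the full
aorta with the 17 right-side vessels attached as parallel terminal leaf
segments at the brachiocephalic origin, an n-furcation the data model
permits. Its role in this package is parameter accounting, not
simulation.

What the generator does **not** emulate: measured per-subject
geometries, vessel curvature and branching angles, viscoelastic wall
behaviour, anatomical variability of the palmar arch, or a measured
aortic-root flow waveform (the analytic half-sinusoid has no late
systolic deceleration or end-systolic backflow). Passing tests therefore
demonstrate the correctness of the algorithms and the qualitative claims
of the reduction method at physiological scales — not agreement with any
particular published parameter set, whose waveform-error percentages
would require that exact data.

## Problem sizes

Default test and acceptance runs use cell sizes of 5–15 mm (at least 4
cells per segment), periodicity tolerances of 3e-4–5e-4 with warm
starts, 1024-point output grids, 100 random trees for the circuit-oracle
check and a 200-compartment chain for the dynamic-equivalence check;
oracle-grade runs (steady states, convergence studies) tighten the
tolerances as documented in the individual tests.

## Known limitations

- Elastic (not viscoelastic) walls; no energy-loss junction models,
  gravity, curvature or 3D coupling.
- The reduction carries no inertance, so reduced models cannot represent
  peripheral flow-acceleration effects; `K2` is reported but unused.
- First-order accuracy at segment-edge cells (probe values at exact
  segment ends are linear extrapolations; the imposed boundary fluxes
  themselves are exact).
- The explicit scheme's time step is set by the stiffest/shortest
  segment; strongly disparate segments make whole-network runs pay that
  cost globally.
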