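# Methods

`ipadflow` asks a quantitative question about the glymphatic/IPAD debate:
if interstitial fluid (ISF) leaves the brain along arterial basement
membranes (BMs), *can the arterial pulse wave supply the driving force*?
The package couples four stages — an inlet waveform, a 1D pulse-wave model
of the middle cerebral artery (MCA) and its first bifurcation, an elastic
transfer of the lumen motion and pressure into the wall, and a
lubrication-reduced Darcy model of the BM film — and measures the
cycle-averaged drainage flux, its direction, and the valve strength needed
to reverse it.

All internal computation is in CGS units (cm, g, s, dyn cm⁻²); only the
reported drainage metrics are converted to μm-based units.

## 1. Inlet waveform (`ipadflow.waveform`)

The inlet boundary condition emulates a transcranial Doppler recording of
MCA blood velocity. The synthetic generator is a documented stand-in, not a
model of any patient:

* a beat template built from exactly-periodic von-Mises bumps — systolic
  peak (centre phase 0.14, sharpness κ=40), dicrotic/reflected bump (0.42,
  κ=25), and a shallow post-systolic shoulder — on an end-diastolic
  baseline of 34 cm s⁻¹;
* per-beat multiplicative amplitude jitter (default 4 % s.d.) on the
  pulsatile component and additive white noise (0.5 cm s⁻¹), sampled at
  200 Hz with a fixed cardiac period T = 0.85 s;
* smoothing exactly as one would treat a measurement: the final 10 beats
  are segmented at the waveform foot (the minimum preceding each maximal
  upslope — the standard pulse-wave fiducial), resampled by cubic
  interpolation onto a common 1024-point period, and averaged
  coefficient-wise in Fourier space (linear, hence identical to the
  time-domain beat mean; verified in tests);
* conversion to volumetric flux Q = v·πR² with a flat-profile factor of 1,
  consistent with the thin-boundary-layer profile assumption of the 1D
  model.

The template amplitudes were chosen once so the converted flux sits in the
literature MCA range — with the default seed: mean ≈ 2.4 cm³ s⁻¹, systolic
peak ≈ 4.0, diastolic minimum ≈ 2.1 — and are frozen in the source
(`_TEMPLATE`). The generator is seed-deterministic. What it does *not*
emulate: beat-period variability, respiratory modulation, Doppler spectral
broadening, or instrument drop-outs; passing tests therefore show the
pipeline's response to a clean periodic physiological drive, not robustness
to clinical artefacts.

## 2. Pulse-wave haemodynamics (`ipadflow.hemodynamics`)

The standard 1D axisymmetric equations for lumen area A(z,t) and flux
Q(z,t):

    A_t + Q_z = 0
    Q_t + ∂z( Q²/A + (f/ρ)·√(A0·A) ) = −(2πνR/δb)(Q/A)
          + (r0'/ρ)·[ 2√A(√π·f + √A0·f') − A·f' ]

with the tube law p − p0 = f(r0)(1 − √(A0/A)),
f = (4/3)(k1·e^{k2·r0} + k3), boundary-layer thickness δb = √(νT/2π), and
blood density ρ = 1.06 g cm⁻³. The taper source is the exact compensation
of the explicit z-dependence inside the conservative pressure flux (we
re-derived it; it matches the standard form term by term). Wave speed
c = √(f/2ρ)·(A0/A)^¼ ≈ 10 m s⁻¹ at the MCA calibre — so one cardiac
wavelength (~9 m) vastly exceeds the 7 cm vessel, which is ultimately why
axial pressure gradients, and hence drainage fluxes, are minute.

Geometry: MCA trunk (radius 0.14 cm, length 7 cm = 50·R_u) feeding two
daughters (0.13 → 0.08 cm over 6.5 / 6.4 cm; the right daughter slightly
shorter to de-symmetrise reflections). Rest radius tapers exponentially
(linear available). Compliance constants k1 = 2.0e7 g cm⁻¹ s⁻²,
k2 = −22.53 cm⁻¹, k3 = 8.65e5 g cm⁻¹ s⁻²; ν = 0.046 cm² s⁻¹.

Scheme: Richtmyer two-step Lax–Wendroff (second order; observed order ≥ 1.9
in tests), Δz = 0.1 cm, Δt = 1e−5 s (CFL ≈ 0.12), vertex-centred, z = 0 at
the inlet. Default run length 8 cardiac cycles (6.8 s total) so the final
beat is settled; the solver tracks the relative L∞ difference of the last
two cycles (≪ 1 %). The inlet flux is ramped over the first cycle to avoid
an impulsive start.

Boundaries. The tube law makes c ∝ A^{−1/4}, so the Riemann invariants are
W± = u ∓ 4c along dz/dt = u ± c, with path sources
dW±/dt = g_u − (1/ρ)∂p/∂z|_A ∓ 4λ±·∂c/∂z|_A (friction plus the explicit
taper terms). Dropping those sources is harmless on a uniform vessel but
produces a steady mass leak at tapered junction nodes; they are included.

* Inlet: prescribed periodic Q(t); A closed by the continuity ghost-flux
  compatibility condition.
* Bifurcation: 6 unknowns (A, Q at the three meeting nodes) solved each
  step by Newton iteration (analytic Jacobian, scaled residual < 1e−12)
  enforcing the three advected invariants, Q_p = Q_1 + Q_2, and pressure
  continuity. Conservation holds to ~1e−16 of peak flux.
* Outlets: three-element Windkessel (R1 = 14.130, R2 = 7.200 g cm⁻⁴ s⁻¹,
  CT = 2.4752e−3 cm⁴ s² g⁻¹, identical at both daughters), capacitor
  advanced by backward Euler, combined with the outgoing invariant into a
  scalar Newton solve for the outlet area.

Solver-internal pressure is the excess over diastolic (the diastolic offset
p0 has zero axial gradient on the trunk and is added only when reporting
absolute pressures).

## 3. Wall mechanics (`ipadflow.wall`)

The BM sits at radius r = a + η·h_w inside the wall (η = 0 lumen, η = 1
outer wall; wall thickness defaults to h_w = 0.1·r0, a physiological
wall-to-radius ratio). Two transfer functions map the lumen state to the
BM position; both follow the classical incompressible thick-walled-cylinder
(Lamé) solution, chosen because it is the canonical "linear elasticity
approximation", analytically testable, and reproduces the expected
monotone decay of drive with depth in the wall. Both are pluggable.

* displacement: ξ = √(A/π) − r0 at the lumen, attenuated through the wall
  by the incompressibility kinematics u(r) ∝ 1/r, giving
  R_i = (a + η·h_w) + ξ·a/(a + η·h_w);
* pressure: the pulsatile radial stress (≈ pore pressure) transfers with
  the Lamé weight w(η) = a²(b² − r²)/(r²(b² − a²)), w(0) = 1, w(1) = 0,
  monotone decreasing — hence drainage is fastest for a BM adjacent to the
  lumen and vanishes at the stress-free outer surface.

The axial gradient p_z is formed by second-order central differences
(one-sided at the ends). There is no feedback from the BM flow to the wall
(the film is far too thin to load the artery).

## 4. BM drainage (`ipadflow.drainage`)

Because the film is thin (W/L ~ 3e−6), the annular Darcy problem reduces to
a 1D conservation law for the BM thickness h_bm(z,t):

    ∂t(γ·R_i·h_bm) = ∂z( R_i·h_bm·K(p_z)·p_z ),   q1 = −K(p_z)·p_z,

with fluid volume fraction γ (default 0.5; no literature value — mean
fluxes scale with 1/γ and a sensitivity sweep over {0.3, 0.5, 1} is part of
the test suite) and rest thickness h_bm0 = 200 nm (physiological; swept
over {100 nm, 200 nm, 1 μm}). The valve is the step mobility K = K0 for
p_z < 0 and K = K1 for p_z ≥ 0 (K1 > K0 > 0), with K1 = k/μ,
k = 1e−10 cm², μ = 1.5e−3 Pa s, so K1 ≈ 6.67e−9 cm³ s g⁻¹. The ratio
K0/K1 is the valve strength; 1 disables the valve.

Discretisation: explicit conservative flux form. The mobility is evaluated
*per face* from the face-centred gradient (exact pressure differences when
the pressure field is supplied), which keeps the valve decision local and
makes the cell-summed fluid volume exactly conserved for the default
no-flux ends (machine precision; verified). Periodic ends are available
for method tests. The hemodynamic output cadence (default 1 ms) is
sub-stepped whenever the advective CFL of the film exceeds 0.4 — for the
physiological drive the effective film velocity is ~5e−6 cm s⁻¹, so no
sub-stepping occurs in practice.

Metrics are trapezoid averages over exactly the final cardiac period at the
mid-vessel node of the MCA trunk (per-node profiles are always attached):
mean volumetric flux Q_bm = 2π·R_i·h_bm·q1 (full annulus, in μm³ s⁻¹),
mean Darcy speed q1 (μm s⁻¹), and two width-variation measures in Å — the
spread along the vessel max_t(max_z h − min_z h), which is the quantity
that drives the flux, and the pointwise |h − h(z, t_ref)|, which is
dominated by the uniform radial squeeze (h ∝ 1/R_i pointwise when the flux
divergence is negligible). Positive flux means the blood-flow direction;
negative means reverse (IPAD) drainage. Because the printed literature
values for this problem mix flux and velocity conventions that are not
mutually consistent with any single annulus area, both Q_bm and q1 are
always reported side by side.

The critical valve ratio is found by bisection of the cycle-mean flux over
K0/K1 ∈ [0.005, 1] to a bracket width of 1e−4; a missing sign change is
reported as an explicit error, never silently.

### 2D oracle (`ipadflow.oracle`)

An independent brute-force check of the lubrication reduction: the full
axisymmetric Darcy problem ∇·(K∇p) = 0 on the annular strip, mapped to the
unit rectangle and discretised as a symmetric 9-point finite-volume system
(sparse direct solve, ≤ 1e4 cells), with Dirichlet pressures at the z-ends
and no-flux sheaths. It is exact for straight annuli with linear pressure
and agrees with the 1D model to O((W/L)²) on manufactured wavy gaps
*provided all geometric slopes scale with the gap* — the slowly-varying
expansion constrains wall slopes, not just the width. A travelling
pressure wave instead is checked against the closed-form second-order
peristaltic rectification ⟨Q⟩ = 2πa·h0·K²k²P²/(2γc), which the solver
reproduces to ~1 %.

## Numerical choices and degenerate inputs

* Junction Newton: initialised from the current state, capped at 50
  iterations, divergence raised with the residual; areas are kept on the
  physical branch.
* CFL is checked every step; violation aborts with a diagnostic rather
  than producing a silently dispersive solution.
* p ↔ A round-trips through the tube law are exact to machine precision;
  non-positive areas, pressures beyond the p0 + f asymptote, degenerate
  Windkessel elements, empty gaps (R_o ≤ R_i) and sub-3-node grids are
  rejected with explicit errors.
* The valve boundary case p_z = 0 maps to K1 (the open branch), matching
  the step-function definition.
* Zero drainage rate in the turnover computation is signalled as an
  infinite turnover, not an exception.

## Problem sizes

Defaults reproduce the study conditions: Δt = 1e−5 s, Δz = 0.1 cm, 8
cycles, ~680 000 steps (≈ 4–5 min on one core); the BM stage runs on the
1 ms output cadence and is negligible, so valve-ratio sweeps and the
threshold bisection reuse one haemodynamic solve. The test suite uses the
same full geometry at Δt = 2.5e−5 s and 5 cycles (settled to ~1e−11
periodicity) as its shared fixture, plus shortened vessels for
solver-behaviour tests; these test-scale choices are the package's own
defaults for its suite and are stated here so their outputs are not
mistaken for full-resolution runs.

## Known limitations

* The wall transfer is a stated Lamé stand-in for a full poroelastic wall
  model; alternative transfer functions can be injected, and all headline
  conclusions (sign structure, orders of magnitude) are insensitive to the
  weight's exact shape, but precise flux values are not.
* The BM film does not feed back on the artery, carries no solute
  (amyloid-β) transport, and has sealed axial ends by default — over very
  long horizons a sealed film must redistribute mass, so cycle-mean fluxes
  are meaningful only on the quasi-static horizon actually simulated.
* One printed Windkessel set serves both daughters; no vasomotion or
  smooth-muscle forcing is modelled (the obvious next candidate driver).
* The turnover-time arithmetic takes the number of contributing arteries
  as an explicit input rather than assuming one.
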