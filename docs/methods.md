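# Methods

`valvedyn` reconstructs a patient-specific aortic valve from six Doppler
echocardiographic dimensions, computes the transient pressure loads on the
leaflets with a lumped-parameter model of the left heart, solves the
dynamic large-deformation mechanics of the three leaflets over a cardiac
cycle, and calibrates the per-leaflet stiffness against image-derived
opening metrics.  This note records the model content, the numerical
choices, and what the synthetic test conditions do and do not demonstrate.

## Parametric valve geometry

The valve is a conical frustum (base diameter `Db` at z = 0, commissure
diameter `Dc` at z = H).  Three commissure points on the top circle are
placed 180° opposite three base construction points with angular spacing
`alpha`, `beta`, `360 − alpha − beta`; each leaflet is defined by the plane
through its two commissures and the remaining base point.  The root
attachment curve is the plane/frustum intersection (closed form: the
intersection is linear in z at fixed azimuth).  The **open** configuration
projects the attachment curve onto the commissure plane M along axes tilted
5.25° from the valve axis (a direct measurement from the source imaging
protocol) and rules a surface between curve and projection.  The
**closed** configuration mirrors the open leaflet across its own defining
plane.  Because the attachment curve lies in that plane, this reflection is
an exact isometry that fixes the root edge — the leaflet can travel between
closed and open configurations without membrane stretch, which is the
essential mechanical property of the classical Thubrikar closure.  The
mutual overlap of the three mirrored leaflets is removed by clipping each
leaflet's rulings at the vertical plane through the shared commissure and
the interior intersection point of the adjacent free edges (computed with
shapely in the plane-M projection).  A coaptation skirt of height `Xs` is
extruded in +Z above the trimmed free edge, tapering to zero near the
commissures where the rulings collapse.

Leaflet thickness is not an imaging output; it defaults to 0.5 mm (typical
human aortic leaflet) and is pinned in every test.  Where a leaflet plane
grazes the base circle (asymmetric valves), the attachment curve is clamped
onto the frustum; this perturbs a single ruling at the 1e-4 relative level.

## Meshing

Each leaflet mid-surface is sampled on a structured grid sized so no
element edge exceeds the configured limit, offset by ± half the thickness
along nodal normals, and the prism layer is split into quadratic
tetrahedra (C3D10) with the minimum-vertex rule that guarantees conforming
diagonals; midside nodes sit at exact edge midpoints so the isoparametric
map is affine.  There is exactly one quadratic element through the
thickness.  Node deduplication is scoped per leaflet — the three leaflets
touch along their coaptation lines in the closed state, and a global merge
would weld the valve shut.  Nodes genuinely shared between leaflets can
only be commissure points; they are clamped with the rest of the
root-attachment band, which also keeps the three leaflet blocks of the
stiffness matrix decoupled.  Meshes are bit-reproducible (sorted,
deterministic insertion).

Boundary face sets: `VENT_*` (ventricular offset surface), `AORT_*`
(aortic offset surface) and `RIM_*` (free-edge band, completing the loaded
boundary).  Mesh export: ASCII VTU, Gmsh MSH 4.1 and Abaqus/CalculiX INP
with C3D10 connectivity and the FIXED node set.

## Leaflet material

Strain energy `U = C10 (Ī1 − 3) + (1/D1)(J − 1)² +
k1/(2 k2) [exp(k2 (I4 − 1)²) − 1]` with a single circumferential fiber
family per element (local cylindrical frame of the valve axis), active only
in tension (I4 ≥ 1) — collagen buckles in compression.  Near-
incompressibility uses ν = 0.475; `D1` follows from the small-strain
consistency `μ = 2 C10`, `κ = 2μ(1+ν)/(3(1−2ν))`, `D1 = 2/κ`.  The fiber
constants are not identifiable from the clinical protocol; the defaults
k1 = 1.5 MPa, k2 = 8 are literature-style exponential-fiber constants,
exposed in the configuration and never touched by the stiffness
calibration (stenotic stiffening is modelled as a purely isotropic
effect).  Density 1.06e-9 tonne/mm³ in the mm–MPa–tonne–s unit system.

## Dynamic finite-element solver

Total-Lagrangian C3D10 elements, 4-point Gauss rule, exact consistent mass
(barycentric monomial integration).  The volumetric penalty uses a
**mean-dilatation (B-bar) treatment**: the penalty pressure is driven by
the element-average Jacobian, with the consistent rank-one tangent
coupling.  Displacement tetrahedra at ν = 0.475 otherwise lock
volumetrically at the element sizes used here, suppressing valve opening
by a factor of ~3.

Loads are follower pressures on the deformed faces: the LV pressure on the
ventricular faces, the aortic pressure on the aortic and rim faces (the
dry assumption — spatially uniform pressures, no fluid coupling; only the
transvalvular difference drives the dynamics).  The load stiffness is
omitted from the Jacobian (it is ~4 orders of magnitude below the material
stiffness here).  Rayleigh damping `C = a0 M + bk K0` with the reference
stiffness `K0`; the stiffness-proportional term (default bk = 5 ms)
represents the viscous resistance of the surrounding blood that the dry
model otherwise lacks, sized so leaflet flutter decays within a few
oscillation periods.  Optional penalty contact keeps each leaflet on its
side of the inter-leaflet planes (the trim planes extended vertically); the
force is C1-regularized over 0.05 mm, each plane is offset so the
reference state is contact-free, and the per-node stiffness scales with
the node's tributary area so the formulation is mesh-objective (default
1 N/mm per MPa of leaflet stiffness per mm², giving micron-level
penetration under diastolic load).

Time integration is the implicit HHT α-method (default α = −0.05,
γ = 1/2 − α, β = (1−α)²/4) solved by Newton iteration with a backtracking
line search and a divergence-guard sub-stepping fallback (local halving of
dt, with recovery).  Linear solves use per-leaflet block sparse LU in
single precision (the factors precondition a double-precision residual);
a factorization is reused across iterations and steps while convergence
stays fast, which is what makes desk-scale cycles affordable.  Convergence
declares `‖R‖ < max(1e-8 N, 1e-5 · ‖f‖)` per Newton solve; the residual
criterion of the reference protocol is interpreted per solve.  Before
t = 0 the cycle-start load is ramped up over a 50 ms settle window
(stepped at twice the nominal dt — equilibration only, not part of the
measured trajectory) so the valve reaches its pressurized late-diastole
state without an impact transient.

## Circulation model

Six sub-models: LV and LA as time-varying elastance chambers (double-Hill
activation, atrial kick late in the cycle), aortic and mitral valves as
regularized Bernoulli orifices (`Δp = 4 v²` in clinical units) with
grade-mapped regurgitant backward areas (0, 0.1, 0.25, 0.5 cm² for grades
0–3 — a documented configurable table, not a claim about any published
mapping), a four-element systemic side (proximal compliance,
characteristic resistance, systemic compliance/resistance) and a
pulmonary-venous pressure source feeding the LA.  The ODE system (four
states) is integrated with LSODA at rtol 1e-8 to a periodic steady state
(cycle-to-cycle state change < 0.03 %), then sampled on a uniform 1000-
point grid.

Calibration is a damped physiological fixed point: pulmonary-venous
pressure pins the end-diastolic volume at a population-normal 165 mL
(consistent with the reported EF 39 % at ~65 mL stroke volume), peak LV
elastance drives the forward LVOT stroke volume, systemic resistance the
mean aortic pressure, the compliances the pulse pressure, and the
activation time-scale the ejection time.  Targets must match within 2 %.
The valve is considered open when forward flow exceeds 5 mL/s (an absolute
threshold; peak-relative thresholds misbehave for spiky flows).

## View metrics and stiffness calibration

The parasternal long-axis view is replicated as the vertical plane through
the mid-sector root attachment points of RCC and NCC; the reference line
A′B′ joins those points (its length is therefore fixed by the geometry —
with synthetic targets produced by the same operator the length matching
is automatic).  A leaflet's angular position is the angle between the
chord from its root point to its free-edge tip in the cut plane and A′B′.
The geometric orifice area is measured in the short-axis plane through the
leaflet junction as the top-circle disk minus the union of the projected
deformed leaflet footprints (shapely).  "Peak systole" is the saved frame
of maximal GOA inside the forward-flow window.

Stiffness calibration bisects `log C10` per leaflet: RCC and NCC against
their angles (absolute error < 1°), then LCC against the GOA (relative
error ≤ 1 %), with up to three outer sweeps for residual coupling.  The
bracket is found by walking geometrically (×4 / ×0.25) from the 0.3 MPa
initial value, and bisection continues until the stiffness bracket itself
is within 2 % — the one-degree angle tolerance alone under-determines C10.
Monotonicity (stiffer never opens further) is audited on the walked
samples and aborts the calibration if violated.  Shortened calibration
simulations run from cycle start to just past peak flow.

## Synthetic patients

`generate_synthetic_patient(seed, severity)` draws truncated-normal
samples of the population statistics: pre-TAVR EOA 0.725 ± 0.135 cm²
(severe), heart rate 70 ± 25.7 bpm, brachial 131.16 ± 26.13 /
61.16 ± 10.46 mmHg, ejection time 0.34 ± 0.04 s, EF 0.39 ± 0.11 (which
with EDV 165 mL sets the stroke volume), BSA 1.7 ± 0.11 m²; post-TAVR
states use the prosthesis size 25 ± 2.83 mm (annulus tied to size),
EOA ≈ 2.0 ± 0.25 cm² (the population table reports no post EOA; patient
examples report 2.0), ejection time 0.29 ± 0.04 s.  Ground-truth leaflet
stiffness samples around the reported per-leaflet means (LCC 0.90,
RCC 1.03, NCC 0.88 MPa pre; ≈ 0.26 MPa uniformly post).  Native geometry
defaults Db 23, Dc 21, H 12, Xs 2 mm, α 118°, β 122°, each sampled ± 10 %.
All randomness flows from one seeded generator; a seed reproduces a
patient bit-exactly.

Because no images ship with the study data, calibration targets are
produced by a forward simulation from the ground-truth stiffness (a
synthetic twin).  Passing the recovery test therefore shows that the
inverse procedure is consistent and well-conditioned — not that the
forward model reproduces any real patient's TTE frames.

## Problem sizes and profiles

Two first-class profiles: `fast` (3 mm edges, dt = 1 ms) and `paper`
(0.62 mm edges, dt = 0.1 ms, the reference resolution).  The test suite
runs the convergence checks at 6 mm vs 3 mm and dt 2 ms vs 1 ms, the
calibration recovery at 5 mm / 2 ms, and the pre/post direction checks at
the `coarse` profile (5 mm / 2 ms); the reproduction script runs the
3 mm → 1.5 mm refinement pair at dt = 1 ms and the dt = 1 ms → 0.5 ms
halving on the 3 mm mesh.

## Known limitations

- At 3–6 mm element sizes the eversion hinge of an opening leaflet cannot
  localize, so absolute orifice areas are several-fold below clinical
  values (tens of mm² instead of ~70–270 mm²).  Convergence ratios and
  stiffness recovery against self-consistent targets are meaningful at
  this scale; absolute GOA is not.
- A consequence of the same resolution limit: valve opening sits in the
  load/stiffness-proportional regime instead of the physiological
  opening-saturated regime.  With one-way circulation→structure coupling,
  a stenotic valve driven by a ~50 mmHg gradient can therefore show a
  larger simulated orifice than a soft prosthetic valve driven by
  ~10 mmHg, reversing the clinical pre/post ordering of GOA and peak
  displacement.  Recovering the clinical ordering requires resolving the
  eversion kinematics (sub-millimeter meshes at ~10× the element count,
  i.e. hours per cycle) or two-way coupling; stiffness orderings are
  unaffected.
- Peak stress fields are not mesh-converged between the 3 mm and 1.5 mm
  levels (changes of order tens of percent); the sub-percent convergence
  of the reference protocol applies to its ~0.6 mm meshes.  Time-step
  sensitivity at fixed mesh is, by contrast, far below the half-percent
  bound here.
- The closed-form parametric closure idealizes coaptation; no leaflet-to-
  leaflet contact search is performed (plane-based penalties only).
- The circulation model is a functional equivalent of the published
  lumped-parameter network, not a re-implementation of its equations;
  only p_lv, p_ao, v_lv, q_av feed the rest of the framework.
- No fluid–structure interaction, no calcification geometry, no coronary
  or right-heart circulation, no baroreflex.
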