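# Model and methods

`icrsfem` simulates the refractive effect of intracorneal ring segments
(ICRS) with a two-dimensional finite-element model of the cornea and a
curvature post-processor. This note records the model, its assumptions, the
numerical choices, and the limits of what the simulations can show.

## Geometry

The corneal cross-section is the band between two circular arcs whose
centers lie on the apex axis: anterior radius 7.8 mm, posterior radius
6.4 mm, separated by the central corneal thickness (550 μm standard, 450 μm
for the thin, keratoconus-like variant). Thickness and depth are measured
along the anterior surface normal. Three layers are carved out of the band:

| layer            | extent                                   | default |
|------------------|------------------------------------------|---------|
| epithelium       | fixed absolute thickness from anterior   | 50 μm   |
| anterior stroma  | fraction of the remaining stroma         | 0.40    |
| posterior stroma | rest of the band                         | 0.60    |

The epithelium thickness, the stromal split, the corneal half-chord
(5.8 mm, i.e. an ~11.6 mm corneal diameter) and the tunnel's radial
position (3.0 mm from the apex axis, a ~6 mm optical zone typical of ICRS
surgery) are documented defaults, all configurable: anatomy gives no single
canonical value and the sources for the remaining parameters do not pin
them down. The stromal tunnel is an 800 × 30 μm band whose mid-height sits
at 70% of the local thickness, measured along the surface normal ("70%
depth" could also be read vertically; the normal reading is used).

Two mechanical idealizations of the 2D section are supported:

* **axisymmetric** — the section revolves about the apex axis; the cornea
  is a hemisphere and the ring a full 360° annulus. This bounds the
  achievable correction from above.
* **plane strain** — the section extrudes; the cornea is a half-cylinder
  with a unilateral segment on one side. This bounds it from below.

## Mesh

A structured quad-8 (serendipity) mesh in surface-angle × depth
coordinates: 7 element rows through the thickness (1 epithelium, 2 anterior
stroma, 2 + 1 + 1 posterior stroma, the middle "1" being a thin band at the
tunnel depth that runs across the whole meridian) and 55 columns per
half-meridian, i.e. 385 elements in the axisymmetric mesh and 770 in the
plane-strain mesh. Column breakpoints conform to the tunnel footprint, so
the tunnel is an exact block of elements that can be deactivated (carved).
Midside nodes are generated by the same surface map as corners, so surface
edges lie on the true arcs. Quadrature is 3×3 Gauss for stiffness and
internal force, 2×2 for the linear solver's stress recovery. Mesh quality
is guarded by a positive-Jacobian check at generation and during assembly;
accuracy by an analytic cross-section-area identity and by Lamé
thick-sphere/thick-cylinder oracles (< 1% at this density, converging under
refinement).

## Material model

Stroma is transversely isotropic with the plane of isotropy spanned by the
two circumferential directions (in-surface tangent and out-of-plane hoop)
and the symmetry axis along the surface normal — stiff along the collagen
lamellae, soft across them:

| layer | E_r | E_c | G_rc | ν_cc | ν_rc | ρ |
|---|---|---|---|---|---|---|
| epithelium (isotropic) | 100 Pa | — | — | 0.4 | — | 1000 kg/m³ |
| anterior stroma  | 500 kPa | 1 MPa   | 20 kPa | 0.34 | 0.34 | 1062 kg/m³ |
| posterior stroma | 400 kPa | 800 kPa | 16 kPa | 0.34 | 0.34 | 1062 kg/m³ |

The reciprocal ratio ν_cr is derived from compliance symmetry
(ν_cr/E_c = ν_rc/E_r) and positive definiteness of the stiffness is checked
at construction. A negative posterior ν_rc = −0.34 appears in one published
transcription of these constants; it is physically unmotivated here and the
positive value is the default, with the literal negative retained behind a
flag for sensitivity checks.

Local material axes at a point are the tangent/normal pair of the ray from
the anterior arc center, rotated into global axes per quadrature point. One
4×4 Voigt operator (xx, yy, hoop, xy) serves both modes: the hoop strain
row of B is u_x/x in axisymmetric mode and zero in plane strain.

**Pre-strain.** The imaged (reference) geometry is already loaded by the
intraocular pressure, so the stroma carries pre-strain: anterior layer
−1.5% radial (compressive) and +1.5% circumferential, posterior layer +1.0%
in both. It is stored with these physical signs and applied as existing
elastic strain, σ = D(ε + ε_pre) — equivalently, a consistent initial-strain
load ∓∫BᵀDε₀ dV — so the reference state carries tensile circumferential
pre-stress (≈ 15–20 kPa, consistent with the thin-shell estimate pR/2t at
15 mmHg). The intraocular pressure (15 mmHg = 1999.83 Pa, conversion factor
133.322 exactly) acts on the posterior surface along its normal.

## Solvers

`solve_static` is the small-strain linear operator: one vectorized
assembly, constraints by elimination (u = Tq + g), one sparse direct solve.
It is exactly superposable and carries the verification battery (patch
test, Lamé oracles, zero-load and equilibrium identities; free-dof residual
< 1e-8 relative in practice ~1e-13).

`solve_incremental` drives the implantation. The imposed boundary
displacements (hundreds of μm in a 550 μm cornea) rotate the meridian far
enough that the dominant coupling — membrane tension resisting and
redistributing transverse deflection, and the arc-length effect of the
ring's bump — is geometrically nonlinear and invisible to a single linear
solve. The driver ramps pressure, pre-stress and imposed displacements in
`n_steps` equal load steps (default 12) and equilibrates each step with
full Newton iterations on the current configuration: the tracked stress
enters the internal force and an initial-stress (geometric) stiffness
(∇Nᵀ σ ∇N on both displacement components, plus the axisymmetric hoop term
σ_hh N_i N_j / x²); coordinates are updated after every iterate. Objective
stress-rate corrections are neglected (strains stay at a few percent, local
rotations moderate), and the Newton tolerance is 1e-7 on the relative
free-dof residual (warning on stall). Pre- and post-operative states are
both computed with this driver so their difference carries no
path-discretization artifact.

Boundary conditions: the limbus is pinned (both translations; a 2D
continuum node has no rotation to leave free), and apex-axis nodes carry
the symmetry condition u_x = 0 in axisymmetric mode. Pressure is applied as
a follower-type load on the current posterior surface in the incremental
driver and as a dead load in the linear one.

## In-silico implantation

The ring cross-section at arc angle φ is an isoceles triangle whose
thickness (height) and base width interpolate linearly along the 160° arc:
150→300 μm and 600→800 μm for the asymmetric design; the thickness-only
(base 700 μm), base-only (thickness 225 μm) and symmetric (225/600 μm)
variants fix one or both profiles.

Implantation at one angular station:

1. **Pre-op**: incremental solve of the uncarved mesh under IOP +
   pre-strain.
2. **Carve**: tunnel elements deactivated (nodes interior to the cavity
   are pinned out of the system).
3. **Impose**: contact-style mapping of the tunnel boundary onto the
   triangle. The base is centered on the tunnel floor when it fits; a base
   wider than the footprint expands the tunnel toward the inner
   (axis-facing) edge, where the radially tensile load would open the
   tunnel in surgery. Floor nodes under the base rest in place, roof nodes
   are projected along the surface normal onto the slants wherever the
   triangle exceeds the 30 μm cavity, untouched nodes stay free. A
   cross-section that fits inside the cavity makes no contact; a zero-size
   cross-section degenerates to "no surgery".
4. **Bind and release**: the contacted nodes form a rigid body (the
   implant is orders of magnitude stiffer than stroma); its radial
   translation and rotation are retained from the imposition and only the
   axial translation is left free, so the ring settles to equilibrium
   under IOP + pre-strain in the incremental solve.

Earlier design iterations mapped the whole tunnel perimeter onto the
triangle outline by arc length; for bases narrower than the 800 μm
footprint this contracts the tunnel floor tangentially — an artificial
hoop squeeze that dominated (and inverted) the central response — and was
replaced by the contact mapping above. Displacement sub-stepping for mesh
validity is subsumed by the incremental driver's ramping.

## Curvature analysis

The deformed anterior surface (mirrored about the apex axis in the
axisymmetric mode) is fitted with a smoothing spline (fixed λ = 1e-7, light
enough to leave analytic circles unbiased to < 0.01 D while suppressing
inter-element wiggle) and resampled on a 25 μm grid over the 10 mm zone.
Sagittal power at station x is P = (n−1)·1000·|y′| / (x√(1+y′²)) dioptres —
the keratometric power of the axial radius — with the apex limit
(n−1)·1000·|y″|; the keratometric index defaults to the clinical 1.3375
(configurable; 1.376 is the common alternative and rescales all powers by
a factor 1.114). Flattening is negative by construction.

The plane-strain model loses the apex symmetry that stabilizes the axial
radius, so for it the power profile inside |x| < 1 mm is replaced by a
degree-1 polynomial interpolation over the supporting annulus 1–3 mm on
both sides (degree 1 reproduces linear trends exactly and cannot overshoot
across the gap).

Summaries of a change profile ΔP(x): the **central** value at the apex, the
**peripheral extreme** (most negative ΔP for 1 mm ≤ |x| ≤ 5 mm, implanted
side only in plane strain), the **central 4 mm zone** mean (the end-to-end
Δ of a design is the absolute difference of this mean between its two end
simulations — zone-mean chosen over pointwise alternatives, both exposed),
and the **best-fit sphere** power change over a 10 mm zone (least-squares
circle: algebraic fit refined geometrically). Design sensitivities (D/μm)
are mean absolute least-squares slopes of the central and peripheral
summaries over the single-parameter sweeps (endpoint finite differences
available as a flag).

## What the simulations do and do not show

All inputs are generated programmatically; there is no measured data and no
randomness anywhere in the pipeline (re-running a study is bit-identical).
The study conditions are the generic corneal geometry and material profile
above — not a keratoconic cornea: the cone itself is deliberately not
modelled (peripheral ring mechanics are insensitive to central shape, and
the thin-cornea variant stands in for ectatic thinning), so results
describe ring-design differences, not patient-level predictions.

Known limitations:

* 2D only. The axisymmetric and plane-strain idealizations bracket a real
  160° segment but neither represents it; angular coupling along the arc is
  absent.
* No viscoelasticity, no fibre-dispersion hyperelasticity, no epithelial
  remodelling (which in vivo smooths exactly the localized sagittal-power
  features this model resolves), no tunnel friction/contact mechanics
  beyond the rigid imposition.
* The absolute dioptre scale of the *central* response is highly sensitive
  to modelling choices that are not pinned down by the available problem
  description (imposition details, solver kinematics, smoothing): with this
  model the imposed bump stays comparatively local and central flattening
  is of order 1–3 D, roughly an order of magnitude below
  proprietary-pipeline figures reported for comparable configurations,
  while peripheral extremes and the thickness-over-width sensitivity
  *ordering* are reproduced. Conclusions should therefore be drawn from
  comparisons between designs, not from absolute central dioptres — the
  same caveat the clinical literature attaches to such models.
* The sagittal-power extremum saturates at −P_pre wherever the post-op
  surface develops a local height maximum (power → 0 at the crest), which
  compresses differences between designs in the peripheral summary.
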