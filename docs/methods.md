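# Methods

`phakosim` simulates the quasi-static mechanics of the human crystalline
lens complex — nucleus, cortex, capsular bag and the three zonular fibre
sets (anterior ZA, equatorial ZE, posterior ZP) — during disaccommodation,
and the effect of pseudoexfoliation zonulopathy on that process. This note
records the model, its assumptions, the numerical choices and their
rationale, and the known limitations.

## Geometry

The lens is an axisymmetric solid of revolution about the optical axis ξ.
Anterior and posterior surfaces are *power caps*

    ξ(r) = ±a (1 − (r/R)²)^q ,   q = R² / (2 a r_pole),

so the cap height `a`, the equatorial radius `R` and the central radius of
curvature `r_pole` can be prescribed independently (q = 1/2 recovers an
ellipse; the caps meet the equator with a vertical tangent, giving a smooth
closed contour). The nucleus is a scaled copy of the same construction
nested inside the cortex.

The published source for the 62-year-old contours is not available, so the
default dimensions are a **one-time calibration** of this parametric
family against the healthy-model deformation outputs:

| parameter | value | note |
|---|---|---|
| thickness | 5.0 mm | accommodated state |
| equatorial diameter | 7.8 mm | effective, see limitations |
| anterior / posterior pole radius | 8.0 / 5.75 mm | central curvature |
| anterior share of thickness | 0.435 | lens centre sits behind the equator plane |
| nucleus thickness / diameter fraction | 0.75 / 0.75 | |

The effective diameter is smaller than anatomical averages (≈9.3 mm); with
the very soft published moduli it is the lever that sets how much of the
0.5 mm zonular stretch reaches the equator. The calibration was fixed once
against the healthy deformation pattern and is not adjusted per scenario.

Zonules are annular membranes of length l_Z = 1.5 mm leaving the capsule
at −10° (ZA), 0° (ZE) and +24° (ZP) to the equatorial plane, all 10 μm
thick. Insertions sit at ±0.6 mm arc distance from the equator (ZE at the
equator). The oval variants scale the vertical vs horizontal zonular
length with an elliptic interpolation in the circumferential angle θ
(θ = 0 superior); the band variants widen the capsular anchorage belt per
the published tables, realised as multipoint ties that average the motion
of all capsule nodes across the band at the same angular station.

## Materials

Units are mm–N–MPa. Nucleus, cortex and capsule are isotropic and
quasi-incompressible (E_N = 0.82 kPa, E_C = 0.04 kPa, E_CB = 1.5 MPa, all
ν = 0.47; densities 1099 kg/m³). In the total-Lagrangian setting the
solids use a compressible neo-Hookean energy

    Ψ = μ/2 (I₁ − 3) − μ ln J + λ/2 (ln J)²,

which linearises to Hooke's law with the published constants but — unlike
Saint Venant–Kirchhoff — stays stable in compression. That matters here:
the lens substance carries stresses an order of magnitude above its own
shear modulus, and the SVK geometric stiffness then destabilises the
Newton iteration.

Zonules follow the Holzapfel–Gasser–Ogden law with one fibre family along
the zonule axis and the published constants (C₁₀ = 0.0583 MPa,
D₁ = 1.0286 MPa⁻¹, k₁ = 0.087 MPa, k₂ = 21.75, κ = 0.3, ρ = 1000 kg/m³);
C₁₀/D₁ are printed unitless in the source and adopted as MPa / MPa⁻¹. The
exponential term is tension-only (standard Macaulay switch). A
`n_families` field allows the two-coincident-family convention of common
FE implementations; the default is one family.

## Discretisation

The half cross-section is meshed with a mapped triangulation (fan + rings
in the nucleus, interpolated layers through the cortex) and revolved in
equal angular sectors; prisms and pyramids are split into tetrahedra with
the minimum-global-id diagonal rule, which guarantees conforming faces.
The sector count is a multiple of 24 so clock-hour dialysis arcs and their
flanks align with element boundaries. Extra contour stations at 0.5, 1.0
and 1.5 mm from each pole keep the central optical zone resolved at any
target edge length. Everything is deterministic — the same inputs always
produce the identical mesh.

* nucleus/cortex: 4-node constant-strain tetrahedra (conforming, shared
  interface nodes);
* capsule: 3-node membrane triangles on the cortex surface (shared nodes),
  plane-stress SVK, plus
  * a *wrinkling relaxation*: compressive principal stresses beyond
    2 kPa are smoothly capped with a 2% residual slope (a bending-free
    membrane cannot carry compression; without the relaxation the capsule
    buckles numerically), exactly inactive around the stress-free state;
  * *discrete-hinge bending* with plate stiffness D = E t³/12(1−ν²) and
    reference dihedral angles as rest angles (energy ½ c_e (θ−θ₀)² per
    interior edge, c_e = D|e|²/(A₁+A₂));
* zonules: 3-node HGO membrane triangles, one radial strip by default, so
  every zonular node is either tied to the capsule or carries the
  prescribed boundary condition (this removes the zero transverse
  stiffness of interior membrane nodes); the through-thickness stretch is
  condensed out by a per-element Newton solve of S₃₃ = 0.

## Boundary conditions and loading

Pole nodes of nucleus and cortex move only along the optical axis. The
zonular outer (ciliary) edges are displaced radially by δ_Z = 0.5 mm in
six equal increments; their other degrees of freedom are fixed. The
published phrase "zonular movement restricted to the radial direction" is
ambiguous about scope; the default here (`zonule_constraint =
"anterior_posterior"`) also restricts the ZA/ZP capsular insertion rings
to radial motion. This reading suppresses the lateral bowing of the lens
that otherwise develops under partial-arc dialysis (the healthy sector
drags the soft lens sideways) and is what makes the accommodation-
amplitude trends monotone in the dialysis extent. `"outer_edge"` (edges
only) and `"all"` (every insertion ring) are available in the protocol.

Gravity, when enabled, acts along superior→inferior as the **immersed
weight** (ρ − 1006 kg/m³): the lens is suspended in aqueous/vitreous
humour, and the full tissue weight applied to a 0.04 kPa cortex would sag
it by millimetres, which is both unphysical and numerically hostile.
`buoyancy_density = 0` restores the full weight. Gravity is ramped in two
sub-increments before stretching; the post-gravity state is the baseline
for all variation metrics.

## Solver

Assembly is vectorised over elements; solid and capsule tangents are
analytic (material + geometric), the few HGO membrane and hinge elements
use central-difference tangents of their analytic forces. Multipoint ties
are eliminated exactly through a sparse transform of the DOF vector.
Each increment is solved by Newton iteration with a backtracking
safeguard (step halving on residual growth or inadmissible states),
relative residual tolerance 1e-6, and automatic increment bisection on
failure. Factorisations (SuperLU) are reused across iterations and
increments until the convergence rate degrades.

## Pathology model

Zonular dialysis reduces the reference membrane thickness over an angular
arc: 5 μm (moderate, 50% of fibres detached) or 0.5 μm core with 5 μm
transitional flanks of one clock-hour per side (severe); 10 μm elsewhere.
The stated extent measures the core arc. The scenario space — five set
groups {ZA}, {ZE}, {ZP}, {ZA,ZE}, {ZA,ZE,ZP} × two severities × five
extents (30…360°) × two origins, with the origin collapsed at 360° —
enumerates exactly 90 models. The pathology sweep runs on the optimised
base configuration (Oval+5.6, Band4) with gravity on.

## Output metrics

ΔT_L and ΔR_L are percentage changes of pole-to-pole thickness and maximal
equatorial radius relative to the post-gravity baseline. F_Z sums the
radial reaction components over the zonular outer edges (mN). Central
optical power uses the thick-lens formula with effective indices
n_l = 1.42, n_p = 1.336 (not printed in the source; physiological
defaults, configurable). The surface radii entering it are, by default,
*plane-averaged sagittal* readings: in every meridian plane through the
optical axis, a circle with a free in-plane centre is fitted to the
deformed cap nodes of that plane's two meridians (over the central 2.5 mm),
and the radii are averaged over the planes. Each single-plane fit is
invariant under rigid rotations — the tilt induced by asymmetric dialysis
does not bias it — and the azimuthal average suppresses the noise of the
non-axisymmetric tetrahedral splitting. A 3D sphere fit, a single-plane
sagittal fit and an axisymmetrised mean-meridian fit are also provided. ΔCOP = COP(baseline) − COP(final step),
reported with the full series because the power is not monotone over the
six steps. Stress summaries (principal ranges, average and maximum
Von-Mises stress, capsule logarithmic strain) are evaluated per element at
the final step.

## Problem sizes

Three mesh presets are used throughout: `smoke` (≈1.8k nodes, seconds per
model run — the resolution of the sweep-level trend checks), `ci` (≈2.4k
nodes — the default working resolution), and `paper` (≈7k nodes — the
resolution of the quantitative readouts, a few minutes per run). The
headline pathological readout (equatorial severe 360° dialysis,
ΔR_L ≈ 4.6%) changes by under 5% between the `ci` and `paper` presets.

## What the synthetic geometry does and does not capture

The generator reproduces the dimensional skeleton of an aged accommodated
lens and the complete zonular/anchorage layout, and it is the only input
the pipeline needs. It does not capture the true (unpublished) refractive-
index-contour geometry, gradient-index optics, capsule thickness
variation, or viscoelasticity. Consequences observed in this
reconstruction, recorded here deliberately:

* The healthy deformation pattern is close to the reference behaviour
  (ΔT_L ≈ 12–13%, ΔR_L ≈ 6–7% vs 14.2%/7.9%), and relative pathological
  effects (e.g. the ≈40% drop of ΔR_L under severe equatorial dialysis)
  track well.
* The total zonular force saturates near 70–80 mN: with the published HGO
  constants, the force the zonules can transmit at the equilibrium equator
  displacement is set by the lens-side resistance, and the published
  134.1 mN is not reachable in this geometry.
* The accommodation amplitude is small and mesh-sensitive (≈+0.7 D on the
  coarse preset, ≈−0.5 D on fine ones, vs +1.57 D): the central-cap
  curvature response of a bending-weak capsule on a near-fluid cortex is
  delicately balanced between flattening (affine stretching) and local
  steepening (rim traction), and the balance point depends on the cap
  shape that the unpublished contours would fix. ΔCOP *differences*
  between scenarios on a fixed mesh are better behaved than the absolute
  amplitude, but equatorial dialysis does shift ΔCOP by up to ≈0.5 D here,
  and the all-sets group shows a ≈+0.4 D excursion at 90° partial-arc
  dialysis — both departures from the reference study's claims are left
  visible in the acceptance suite rather than hidden.

## Degenerate inputs and tie-breaks

Zero dialysis extent reproduces the healthy model bit-for-bit; zero-width
anchorage bands degenerate to single-node ring ties; a 360° severe arc has
no flanks. Meshing rejects non-positive edge lengths, sector counts not
divisible by 24, overlapping anchorage bands and inverted elements (the
offending element is named). The plane-stress Newton solve starts from the
incompressible guess and damps steps that would leave the admissible
range.
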