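# Methods

## Model overview

`zonula` solves one small-strain linear elasticity problem per run: a
quarter model of the crystalline lens, suspended by discrete zonular
fibres, loaded by prescribing a 0.5 mm radially outward displacement at
every fibre free end. The package then measures what an ophthalmic
stretching study reports: paraxial radii of curvature before and after the
stretch, axial thickness, central optical power (COP) via the thick-lens
equation, and the displacements of the two poles and the equator.

Units are mm / N / MPa throughout the solver; lens-layer moduli are stored
in kPa, as conventionally tabulated, and converted to MPa exactly once at
assembly.

## Synthetic lens geometry

True lens meridional profiles would come from tomography of individual
lenses; those images are not available, so the geometry module generates
profiles that match the quantities a study prints — the paraxial radii, the
power, and typical adult dimensions — with a closed-form surface family.

Each surface is an even-aspheric sag curve measured from its pole,

    h(r) = s_max · [1 − √(1−u²) · (1 + ψ₂u² + ψ₄u⁴)],   u = r/a,

where `a` is the equatorial radius and `s_max` the pole-to-equator axial
distance of that side. ψ₂ and ψ₄ are fixed in closed form so the Taylor
expansion of `h` matches a sphere of the prescribed paraxial radius through
fourth order; the √(1−u²) factor closes the contour at the equator with a
vertical tangent (the contour point with 0° tangent slope), giving C1
continuity between the two sides. When the prescribed radius, semi-diameter
and sag are those of a spherical cap, the surface degenerates to that exact
sphere — a useful analytic check. A two-piece conic-plus-tangent-arc
construction was considered and rejected: for steep surfaces (the symmetric
lens) the tangent arc cannot span the equatorial gap, and a vertical-tangent
conic distorts the paraxial zone enough to bias the ±1.5 mm circle fit by
~2%, which would contaminate the initial power.

Defaults, chosen once as representative of an adult lens and overridable in
the study configuration:

| parameter | asymmetric | symmetric | basis |
|---|---|---|---|
| rₐ / rₚ (mm) | 10.96 / 6.94 | 5.33 / 5.00 | study prescription |
| thickness (mm) | 4.408 | 4.343 | back-solved so the undeformed COP is 19.48 / 31.75 D (the thick-lens equation is linear in t, so the inversion is exact) |
| equatorial diameter (mm) | 9.2 | 9.2 | typical adult lens |
| equatorial-plane offset (mm) | −0.35 (anterior) | 0 | the asymmetric lens's steeper posterior surface places its equator anteriorly |
| nucleus fraction | 0.5 | 0.5 | relative scale of the nucleus contour |

The 12 cortical layer boundaries are affine scalings of the outer contour
about the centre of the equatorial plane, at equal scale increments from
the nucleus fraction to 1. This guarantees strict nesting. Real
iso-indicial contours are not exact affine copies of the surface; the
consequences are discussed under limitations.

Zonular geometry: three sections of 17 fibres per quarter model, spaced
uniformly in azimuth from 0° to 90° inclusive; each fibre is 1.5 mm long
and 0.025 mm in radius. The equatorial section inserts at the equator and
runs radially; the anterior and posterior sections insert at a configurable
axial distance from the equatorial plane (interpreted as perpendicular
distance, not arc length) and run outward at 15° to that plane, directed
away from the equator on their own side. Named combinations:
A (1.0, 1.2), B (1.0, 1.6), C (1.0, 1.0), D (1.0, 1.4) mm
(anterior, posterior).

## Materials

| component | E | ν | geometry |
|---|---|---|---|
| nucleus (layer 1) | 0.6 kPa | 0.49 | innermost region |
| cortex layers 2–13 | 1.1 … 6.6 kPa, +0.5 kPa/layer | 0.49 | 12 shells; cortical mean 3.85 kPa |
| capsule | 1.5 MPa | 0.47 | 6 µm membrane skin |
| zonule | 0.35 MPa | 0.47 | bars, A = π·(0.025 mm)² |

The stiffness ladder is stated in kPa; a source stating "MPa per layer"
for the same table is inconsistent with its own cortical average of
3.85 kPa, so kPa is used. All behaviour is linear isotropic elastic — only
a Young's modulus and a Poisson ratio are assigned to each component.

## Mesh

The meridional half-section is gridded by scaled copies of the outer
contour (rings) crossed with stations placed by arc length along the
contour, then swept through 90° of azimuth. Because ring boundaries are
exactly the layer contours, every hexahedron lies in exactly one stiffness
layer. Cells touching the optic axis or the centre collapse to wedges/tets
(repeated node ids), which trilinear elements integrate with non-negative
Jacobians. The nearest meridional station on each side is moved exactly
onto the zonular insertion point, so an insertion node ring exists at every
resolution.

Default resolution is 40 meridional stations × 16 target radial
subdivisions (8 nucleus rings + one ring per cortical layer) × 16 azimuthal
intervals ≈ 12,800 hexahedra — a desk-scale problem that a direct sparse
factorisation solves in seconds. The azimuthal count is a multiple of 16 so
that the 17 fibre azimuths (spacing 90°/16) coincide with mesh azimuth
lines; this removes load-placement discretisation error and is also why the
mesh-independence ladder (28×12×16, 40×16×16, 56×22×16) refines the
meridional/radial grid at fixed azimuthal count.

The capsule is skinned onto the outer hex faces as conforming membrane
quads. Each zonular fibre becomes a 2-node bar whose lens end snaps to the
nearest capsule node; capsule nodes within the tie radius of that master
are constrained to translate with it. Patches are disjoint (each capsule
node joins its nearest master only), so the tie graph has no chains. The
tie radius defaults to a fixed 0.5 mm — about the azimuthal spacing of
adjacent fibres at the equator — rather than a multiple of the local mesh
spacing, because a mesh-dependent radius changes the physical insertion
footprint under refinement and prevents mesh convergence.

## Elements and solver

* Hexahedra: trilinear displacements, 2×2×2 Gauss quadrature, B-bar
  (mean-dilatation) volumetric treatment. At ν = 0.49 fully integrated
  trilinear bricks lock volumetrically; a regression test verifies that the
  bending stiffness of a slender slab at ν = 0.49 stays within 5% of the
  ν = 0.3 reference with B-bar and exceeds it by >15% without.
* Capsule: 4-node membrane quads — plane-stress stiffness × thickness in
  the local tangent plane at each Gauss point, no bending (the bending
  rigidity of a 6 µm film is negligible). Degenerate (collapsed-corner)
  quads at the poles skip zero-area Gauss points.
* Zonules: axial truss bars, k = EA/L. Bending stiffness of a 25 µm fibre
  is negligible under axial stretch.
* Constraints: symmetry planes lose their normal displacement; the node at
  the centre of the equatorial plane is fixed in all DOF; each fibre free
  end has all three components prescribed (radial = stretch, azimuthal =
  axial = 0); tie patches are eliminated master–slave. Prescribed and tied
  DOFs are substituted before factorisation (u = T·u_f + u_p), and the
  reduced system is solved with SuperLU (COLAMD ordering, deterministic).
  A pivot-ratio check (<1e−10) reports remaining rigid-body modes.
* Diagnostics per solve: relative residual (≤1e−9 demanded), strain energy
  vs ½·Σ reaction·prescribed-displacement (work–energy balance, agrees to
  1e−8 relative), reactions exported per node.
* Stress recovery: one point at the element centroid with the B-bar
  consistent operator, no nodal averaging; von Mises = √(3J₂).

Verification: patch test to machine precision; unit-cube uniaxial and bar
closed forms to 1e−9; plane-strain thick-walled (Lamé) quarter-disc
benchmark within 1%; linearity/scaling and rigid-body checks.

## Optics

Surface nodes of each side inside the central 6 mm zone are extracted with
their deformed coordinates. Radii come from a least-squares circle over the
±1.5 mm paraxial band: a Kåsa algebraic fit seeds a geometric
(orthogonal-distance) Levenberg–Marquardt refinement; surface points are
mirrored across the axis so the fitted centre is unbiased. An even
polynomial sag fit (orders 2 and 4) over the full 6 mm zone is exported for
inspection only — powers use the circle radii exclusively. Axial thickness
is the deformed pole-to-pole distance. Powers use the thick-lens equation
with both radii as positive magnitudes; a paraxial ray-transfer-matrix
computation provides an independent oracle (agreement to 1e−9 D).

Pole shifts are |axial displacement| at the surface pole nodes; the
equatorial shift is the radial displacement of the equator node on the y=0
symmetry plane.

## What the generator emulates — and what it does not

The synthetic geometry reproduces the printed paraxial radii (fitted
recovery within 0.5%), the undeformed powers (exactly, through thickness
calibration), plausible adult dimensions, strict layer nesting, and the
stated zonular geometry. It does not reproduce individual tomography
profiles: mid-surface asphericity beyond fourth order, the true equatorial
tip shape, and the true iso-indicial layer contours are all synthetic.
Passing quantitative tests therefore demonstrates internal consistency of
the pipeline on a faithful stand-in geometry, not agreement with any
individual lens.

This matters for quantitative comparison with published stretching results
on real lens shapes. With the defaults above, the simulated power losses
(≈5.4/7.0 D for the asymmetric lens, ≈8.5/10.6 D for the symmetric) exceed
the published commercial-solver envelopes for the equivalent experiment
(≈2.7–3.9 and 6.3–7.6 D) even though every element-level benchmark passes,
the solve is converged (<2% power-change variation between the two finest
mesh levels) and the qualitative structure — power loss growing by ~1 D or
more when the posterior insertion moves away from the equator, a smaller
equatorial shift and larger anterior pole shift at the far insertion, and a
larger power loss for the steeper lens — is reproduced. The dominant
difference is the deformation mode of the central caps: in this model the
flat central surfaces dimple inward (the capsule-dominated surface is
transversely softest where it is flattest), while the published fields
translate the caps nearly rigidly. Probes that were tried and did not close
the gap: a one-shot membrane stress-stiffening re-solve (~1% effect),
nucleus fractions 0.35–0.65 (<15%), tie radii 0.31–0.9 mm (±15%),
along-fibre instead of radial loading (worse), and refinement to 20k
elements (~5.4 D converged). The remaining candidates are the true
tomography profiles and iso-indicial layer shapes, and commercial-solver
formulation details, neither of which is reproducible here.

## Numerical choices

* Thickness calibration: exact linear inversion of the thick-lens formula;
  a target power above the zero-thickness limit raises an error, equality
  returns t = 0.
* Layer lookup: half-open scale bins [s_{k−1}, s_k); the containment scale
  of a point is found by bisection along the ray from the lens centre.
* Circle fits require ≥3 points; collinear or coincident input raises.
* Arc-length tables use 2000 samples per side (node placement accurate to
  ~1e−6 mm); insertion stations are snapped exactly.
* Degenerate elements: collapsed hexes are accepted with non-negative
  Jacobians; any negative Jacobian aborts assembly naming the element.
* Determinism: no randomness anywhere in the pipeline; identical
  configurations reproduce results bit-for-bit (the study seed is reserved
  for future stochastic fixtures and recorded in manifests).

## Known limitations

* One linear solve: no geometric nonlinearity, no follower forces, no
  incremental stretch. At 0.5 mm stretch the capsule strains reach ~5%,
  beyond the strict small-strain regime.
* The capsule has uniform 6 µm thickness; real capsules are several times
  thicker anteriorly than posteriorly.
* Zonular fibres are straight, unpretensioned axial bars tied to rigid
  translation patches; fibre bending, pretension and capsule-fibre
  compliance are not modelled.
* Layer contours are affine scalings; real gradient-index contours are
  flatter axially, which plausibly stiffens the polar caps (see above).
* Stress maxima are exported for inspection but carry no quantitative
  claims; centroid recovery on collapsed axis elements is first-order.
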