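# Methods

`sacroplan` implements the computational workflow for planning revision
screw fixation of the sacrum when a broken screw fragment blocks the
standard corridor: building a patient-specific heterogeneous finite-element
model from calibrated CT, comparing the pull-out stiffness of candidate
screw trajectories, generating a drill-guide template, and auditing drilled
trajectories against the virtual plan. Because no clinical dataset ships
with the package, a synthetic phantom module generates every input with
known ground truth; all quantitative claims in the test suite refer to that
synthetic bench.

## Synthetic QCT phantom

The bone stand-in is a parametric solid: an elliptic extrusion (the
"body", half-axes 25 x 18 mm, height 40 mm at full scale) with a flat
cranial cap playing the role of the S1 endplate, united with a lateral
ellipsoid wing (the "ala", radii 18 x 12 x 9 mm). It is not an anatomical
mesh; it is the smallest geometry that realizes the two clinically
distinct corridors:

* **S1 convergent** — enters the posterior cortex, crosses the body,
  exits the anterior cortex: a *bicortical* path (the axis crosses the
  cortex twice over the screw length);
* **ALA divergent** — runs laterally into the ala and ends inside bone:
  a *monocortical* path (one cortex crossing).

A cortical shell (1.5 mm at full scale, density 1.2 g/cm^3) surrounds a
trabecular interior (0.28 g/cm^3 in the body, 0.12 g/cm^3 inside the ala —
the sacral ala is notoriously low-density, and this asymmetry is what makes
the stiffness comparison non-trivial). A cylindrical broken-screw fragment
(3.5 mm diameter) sits in the body near the S1 corridor. An in-line
calibration insert with five rods of equivalent BMD 0, 0.05, 0.10, 0.15,
0.20 g/cm^3 lies caudal to the bone. The published rod list contains an
obvious monotonicity typo in its second value; 0.05 g/cm^3 is used and the
list is configurable.

HU values are produced by *inverting* a known ground-truth linear
HU-density law (the same form the calibration stage later fits), adding
i.i.d. Gaussian HU noise (default sd 15 HU). Metal (fragment, drill bits)
renders at a fixed saturated 3000 HU: only its geometric role matters, and
real implant HU is scanner- and kernel-dependent anyway. Partial volume is
approximated by 2x supersampling per axis. What the phantom deliberately
does **not** emulate: beam hardening, metal streak artifacts, anisotropic
trabecular texture, anatomical shape variation. Tests passing on this bench
therefore validate the *pipeline mathematics* (calibration, meshing,
solving, registration, measurement), not robustness to clinical image
artifacts.

Default voxel size is 0.6 mm isotropic, the clinical protocol value. The
finite-element studies run on a geometrically scaled phantom
(`PhantomSpec.small`, scale 0.55, 1.0 mm voxels) so that the whole
two-trajectory comparison and the nine-size refinement study stay within
minutes on one CPU; the corridors, shell topology and material contrast are
unchanged by the scaling.

## Material mapping

Two chained linear laws, applied per element:

* rho_app = -0.0829 + 0.0026 * HU  [g/cm^3], the packaged clinical
  calibration; in the pipeline this law is *refit from the phantom rods*
  (ordinary least squares on eroded rod-interior means) rather than taken
  on faith, and the refit is exact to 1e-10 on noise-free phantoms.
* E = -34.7 + 3230 * rho_app  [MPa], the Kopperdahl-type correlation,
  with Poisson's ratio 0.3.

The modulus law crosses zero near rho_app = 0.0107 g/cm^3, so mapped moduli
are clamped below at `e_min` (default 0.01 MPa) to keep the stiffness
matrix positive definite. Element HU is the mean over voxel centres falling
inside the element (trilinear interpolation at the centroid as fallback for
elements smaller than a voxel); voxels at or above 2000 HU are excluded
from bone means so the metal fragment cannot inflate neighbouring bone
stiffness. No modulus binning is applied in memory — each element keeps its
own E; the Abaqus export bins to 6 significant digits only to keep decks
readable. Screw and fragment elements get titanium-alloy constants
(E = 114000 MPa, nu = 0.3) regardless of image content.

## Geometry pipeline

Segmentation is deterministic morphology: HU window, largest 26-connected
component, then slice-wise 2D hole filling (preserving each slice's outer
contour) — replacing the manual erase/paint steps of clinical software so
runs are reproducible. Surfaces come from marching cubes at the 0.5 level
in world mm (voxel index -> mm via origin + index * spacing). Smoothing is
the Taubin shrink/inflate filter; with 6 iterations at factor 0.7 the
inflate weight mu = lambda / (1 - 0.1 lambda) keeps enclosed volume changes
at the percent level ("shrinkage compensation"). Uniform remeshing is the
classic split / collapse / flip / tangential-relax loop with re-projection
onto the input surface; edges whose dihedral exceeds the sharp-angle
threshold (default 60 deg) are feature constraints whose vertices move only
along the feature polyline, so box-like 90-degree edges survive remeshing
to within floating-point error.

The screw is a surface of revolution (shaft 6.5 x 45 mm, monoaxial head
11 x 10 mm by default): thread rendering exists for visualization but the
FE geometry uses the smooth shaft, consistent with the bonded-interface
idealization below. Bicortical vs monocortical placement is decided
operationally by counting axis/cortex crossings over the screw segment
(entry included): >= 2 is bicortical. Fragment clearance is the minimum
distance between the analytic screw solid and the fragment surface.

## Finite-element model

No external tetrahedral mesher is used: the assembly is meshed on a
structured Cartesian grid at the requested element size, each cell labelled
bone / screw / fragment / void by exact point-in-solid tests against the
watertight part surfaces, and each kept cell split into six tetrahedra
around its main diagonal (Kuhn split — conformal across cells by
construction). Corner tets are promoted to straight-edged 10-node
quadratic elements with shared midside nodes. This is the standard
voxel-mesh practice of image-based bone FE; its staircase boundary is the
price for robustness, and the convergence study quantifies the associated
discretization error directly. Because screw and bone cells share grid
nodes, the bone-implant interface is rigidly bonded — the merged-node
realization of a tie constraint (kinematically identical to a tie for
matched meshes). One consequence is a single element size per model rather
than a graded interface refinement; the nine-size sweep (2.0 ... 6.0 mm)
varies that single size.

Elements are isoparametric tet10 with constant Jacobian and a 4-point
Gauss rule. Boundary conditions reproduce the pull-out bench: all three
displacement components fixed on the cranial endplate cap (surface nodes
within about one cell of the maximal axial coordinate) and on the caudal
third of the bone surface; a 500 N tensile load along the screw axis on
the free-surface nodes of the screw head. Two load distributions are
implemented: equal nodal forces (the default for the screw head, whose
loaded patch is only figural) and a consistent uniform-traction
distribution over quadratic boundary faces (zero at corners, one third per
midside) used by the verification problems, where the uniform-stress
solution is then reproduced to machine precision. Pull-out stiffness is
k = F / mean |u| over the nodes in the middle third of the head's axial
extent.

The assembled system is solved directly via SuperLU with symmetric-mode
minimum-degree ordering (`MMD_AT_PLUS_A`), which keeps fill-in tractable up
to roughly 10^5 DOF on a single core; an ILU-preconditioned CG fallback is
available for larger systems. The solver is verified against closed forms
(uniaxial bar to 0.1%, slender cantilever vs Euler-Bernoulli to 5%), an
independent dense B-matrix assembly (agreement to 1e-8), global reaction
balance (1e-6 relative), linearity (doubling E doubles k) and frame
invariance. Convergence is declared when the mean head displacement changes
by less than 2% (configurable) between consecutive refinements — the
criterion itself is a package choice, as the underlying study only reports
the element count where its curves flatten.

On the default synthetic bench the convergent bicortical trajectory is
roughly 1.2-1.6x stiffer than the divergent monocortical one at the
resolutions the shipped studies use (the coarsest sweep models are
mesh-noise dominated and their stiffness values scatter strongly — visible
in the convergence tables). The ordering is asserted in tests at the
finest sizes; the ratio is reported but not asserted, since its value
depends on the phantom's density contrast, not on a clinical measurement.
The FE screw is the smooth shaft plus an axial loading stub: the wide
tulip head is omitted from simulation geometry because on a voxel grid it
would weld to the dorsal cortex (the merged-node tie knows no contact),
and shaft cells are reinforced along the planned axis so even the
coarsest sweep models keep a connected one-cell load path.

## Drill-guide template

The guide is an offset shell (default 3 mm) of a dorsal/cranial contact
patch of the bone surface, selected by face normal direction and an axial
window, carrying one hollow tube per trajectory (inner diameter = drill
bit 2.5 mm + 0.2 mm clearance) coaxial with the planned axis. The solid is
composed implicitly — min/max of the shell slab function and analytic
cylinder SDFs, bores subtracted — and triangulated by marching cubes
(default pitch 0.45 mm), which yields a watertight, printable mesh whose
genus equals the number of tubes by construction. A self-audit fits a
cylinder to the bore surface and checks coaxiality with the plan
(< 0.1 deg on a flat-patch bench). Tube length and standoff are exposed
parameters; the source study never quantifies them.

`compare_cast_to_pattern` is the part-comparison instrument: signed
distance from each vertex of one mesh to the other's surface (negative
inside), with summary statistics and a colour value clipped to +-1 mm for
rendering.

## Accuracy instrument

`evaluate_drilling` mirrors the physical validation loop: threshold the
post-drill scan for metal (6-connected labelling, with erosion retries if
nearby bits touch), register the scan to the planning frame (closed-form
Kabsch landmark fit with reflections excluded, refined by trimmed
point-to-plane ICP, 90% inliers, 1e-4 mm RMS convergence; the scan-side
surface is a greyscale HU isosurface rather than a binary-mask contour,
which localizes the surface to a fraction of a voxel and removes a
~0.1-degree rotation bias), fit each bit's axis as the principal direction of its voxel
cloud (adequate at drill-bit aspect ratios; the Monte-Carlo tests bound the
error at 0.5 deg under 0.05 mm point noise), match bits to plans by a
combined angle + entry-distance cost (Hungarian assignment), and report per
trajectory the 3D line-to-line angle alpha = arccos |a.b| (orientation-free,
in [0, 90] deg), the entry offset, and a Gertzbein-Robbins grade.

Grading uses the scale's standard 2 mm bands on the maximal distance by
which the virtually implanted screw cylinder protrudes outside the safe
corridor (the bone solid by default). Two operational choices deserve
note. First, the oblique entry funnel and — for intended bicortical paths —
the planned exit region are excluded from breach sampling (one screw
diameter margin): every obliquely inserted screw's cylinder leaves the
surface at its entry, and a planned transcortical tip is not a misplacement.
Second, protrusions below the instrument's surface-localization resolution
(half a voxel of the scan, e.g. 0.3 mm at 0.6 mm voxels) grade as A: they
are below what voxel-derived corridor surfaces can attest. Both exclusions
affect the grade only; the raw breach value is always reported.

## Numerical and degenerate-input policy

Rigid transforms are validated orthonormal with det +1 at construction;
axis directions are unit-normalized and treated as orientation-free.
Degenerate inputs raise rather than warn: empty segmentation windows,
collinear landmarks, isotropic point clouds in the cylinder fit,
under-constrained FE systems, non-watertight remesh inputs. Determinism is
a contract: one seed drives every stochastic component (phantom noise,
sub-seeds for the evaluation bench), and reruns with identical config
reproduce summary JSONs bit for bit; FE, geometry and registration stages
contain no randomness at all (ICP samples its source points from a fixed
seed).

## Problem sizes used in the shipped studies

The demo pipeline and acceptance studies use the scale-0.55 phantom at
1.0 mm voxels: FE models of roughly 5-20 x 10^3 tet10 elements
(2-9 x 10^4 DOF), the nine-size sweep per trajectory, guide generation at
0.45 mm marching-cubes pitch, and post-drill volumes of ~150^3 voxels.
These sizes were chosen so the full suite, demo and acceptance studies all
complete in minutes on one core while leaving every qualitative result
(corridor topology, stiffness ordering, sub-degree angle recovery) intact.

## Known limitations

* Voxel meshing cannot grade the interface to 0.6 mm while keeping the
  far field coarse; interface fidelity is bought only by global refinement.
* Linear elasticity with a bonded interface: no contact, friction,
  thread purchase, plasticity or pull-out failure — stiffness comparisons,
  not strength predictions.
* The phantom's two-density trabecular field is a caricature; absolute
  stiffness values have no clinical meaning, only the trajectory contrast
  does.
* PCA axis fitting assumes elongated clouds; it refuses rather than
  degrades on isotropic ones.
* Wall-clock solve times are logged but never asserted; they are
  hardware facts, not results.
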