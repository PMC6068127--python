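# Methods

`tibiamech` reimplements a QCT-based, subject-specific finite-element (FE)
workflow for the proximal tibia: calibrated density volumes are segmented,
re-aligned to a neutral standing orientation, meshed, assigned
density-derived elastic moduli, solved under single-leg-stance boundary
conditions, and summarized as regional stress/strain means, compartmental
stiffness, short-term precision (CV%RMS) and OA-vs-normal comparison
statistics.  Because the clinical CT scans behind the original workflow are
not publicly deposited, the package ships a synthetic knee phantom that
plays the role of the scanner: every stage is exercised end to end on
volumes whose ground truth is known.

## Synthetic knee phantom

The phantom is built from implicit parametric primitives, not an anatomical
atlas: a proximal tibia with superellipsoidal cross-sections, a metaphyseal
flare, two condylar dishes and an intercondylar spine bump; a distal femur
with two condylar ellipsoids and a shaft; a fibula; a soft-tissue envelope;
and a three-rod calibration insert (0, 200, 400 mg/cm3 K2HPO4) under the
limb, mirroring solid reference phantoms used clinically.  Default voxel
size is 0.625 mm isotropic.  Bone intensities combine an 850 mg/cm3
cortical shell (3 mm, blended over 1 mm), a trabecular template that decays
from ~230 mg/cm3 under the plateau to ~120 mg/cm3 in the shaft, and
band-limited Gaussian heterogeneity (15 mg/cm3 SD after smoothing).
Intensities are stored in HU through a generative linear calibration
(0.75 mg/cm3 per HU), which the pipeline must recover from the rods.

Cohort defaults are the study conditions the pipeline emulates: body mass
101 +/- 16 kg (OA) vs 72 +/- 13 kg (normal); OA knees get a 175 degree
femoral-tibial inter-axis (varus) template and a medial density elevation.
A positive varus tilt lowers the medial femoral condyle, narrowing the
medial joint space, so varus loading concentrates medially as in a varus
knee.  The OA medial density multiplier defaults to 1.15: the original
report found no significant OA/normal BMD difference but a consistent
medial trend, so a mild (15%) elevation was chosen once as a plausible
"elevated but individually non-significant" effect; it is a free parameter
of the generator (`density_scale`).

Repeat scans apply an independent 6-DOF rigid transform (Gaussian
translation/rotation, default 1 mm / 1 degree SD) with linear resampling
plus additive Gaussian HU noise (default 10 HU).  Per-repeat RNG streams
are derived from the master seed by counter, so a spec + seed is
bit-reproducible.  The phantom does not emulate CT physics (beam hardening,
scatter, PSF), cartilage or menisci, osteophytes or cysts; passing tests
demonstrate the pipeline's internal correctness and sensitivity to the
modeled factors, not segmentation robustness on pathological clinical
images.

## Image processing

* **Calibration** — nominal rod density is regressed linearly on mean rod
  HU (rims eroded by one voxel); the fit must use >= 2 rods with distinct
  means; the whole volume is converted to mg/cm3 K2HPO4.
* **HMH threshold** — the segmentation threshold is the half-maximum-height
  level: background + 0.5 x (cortical peak - background), the intensity of
  a voxel half-filled with cortical bone and half with joint space.  Levels
  are medians of two probe regions; an automatic placement (cortical = top
  0.5% of the histogram, background = soft-tissue voxels within 10 mm of
  them) replaces the operator-driven step, with explicit masks as override.
* **Segmentation** — thresholding, 26-connected components, seed-based
  assignment to tibia/femur/fibula, one-voxel morphological closing and 3D
  hole filling so sub-threshold trabecular interiors stay inside the bone
  mask.
* **Axes** — the tibial axis is a best-fit line through cross-section
  centroids at the distal end, 50%, 66% and 80% of the imaged extent (the
  scan is cropped, so the imaged distal end stands in for the ankle).  The
  femoral axis is fit through up to 32 shaft cross-section centroids taken
  in slabs (at least 1.5 mm thick) over the 50-90% band of the femoral
  extent — above the condylar mass, below the obliquely clipped image
  boundary — with partially clipped slabs dropped by a completeness filter.
* **Re-alignment** — the minimal rotation takes the normalized average of
  the two axes to vertical, after which both axes make half the supplement
  of the inter-axis angle with vertical (175 degrees -> 2.5 degrees each).
  The rotation's free axial-twist component is fixed by aligning the
  mediolateral principal axis of the proximal tibial footprint with +x, so
  medial/lateral splits are deterministic.  Density is resampled linearly,
  labels with nearest-neighbour.

## Mesh and materials

The default mesh is `hex_voxel`: the segmented grid is coarsened onto a
cell lattice (2 mm bone cells by default) anchored at the tibial apex and
plateau centroid; cells with a majority of bone subsamples become bone
elements.  Non-bone cells inside a vertical cylinder spanning the
femorotibial gap (radius 1.1 x the maximal condylar half-width) become
nearly incompressible soft tissue (E = 10 MPa, nu = 0.495) standing in for
cartilage and menisci; bone and soft tissue share nodes (bonded contact).
Surface nodes are then projected onto the smooth segmented surface (signed
EDT gradient, deviation below one voxel — the same contract as the
surface-smoothing step in clinical mesh pipelines) and interior nodes are
relaxed by a few Laplacian iterations; the operation backs off if any
trilinear corner Jacobian would turn non-positive.  The model is cropped to
the distal 35 mm of the femur and the proximal 65 mm of the tibia/fibula:
the femur is rigid and the crop planes stay more than 25 mm from the
deepest analyzed band, so proximal-tibia fields are unaffected while the
system stays desk-scale.  A `tet_quadratic` mode (Kuhn 6-tet split with
midside nodes, Abaqus C3D10 export) mirrors clinical practice and feeds the
INP writer; the hex path is the default because structured hexahedra are
deterministic and fast at desk scale.

Bone modulus follows the Goulet power law E = a (rho/1000)^2.1 with a
1 MPa floor, rho sampled as the mean of the calibrated density at the
element's integration points.  The exact coefficient of the original
equation is not reproduced in the main text of the source study, so
`coeff_a` is a prominent configuration value; its default (30 000 MPa per
(g/cm3)^2.1) keeps the maximum bone modulus near the ~25 GPa envelope for
cortical BMD around 0.9 g/cm3.  An optional linear pre-transform maps
K2HPO4-equivalent BMD to the density measure the law expects (default
identity).  Bone nu = 0.3; the femur is "rigid" as a stiff elastic solid
(E = 500 GPa), exactly as modeled in the source workflow, not as a
constraint set.

## Solver

Standard isoparametric elements: 8-node hexahedra with 2x2x2 Gauss and a
mean-dilatation (B-bar) treatment of the volumetric strain — without it the
nearly incompressible soft-tissue layer locks and its stiffness becomes
strongly mesh-dependent — and 10-node tetrahedra with the 4-point rule.
Boundary conditions model single-leg stance: the femoral top surface is
fixed transversely and displaced 1 mm downward; the most distal tibial and
fibular sections are fully fixed.  Systems up to 30 000 DOFs are solved by
direct sparse factorization; larger systems by Jacobi-preconditioned
conjugate gradients (rtol 1e-9, direct fallback).  The equilibrium residual
is checked against 1e-8.  Element tensors are reported at centroids; the
von Mises equivalent strain uses the (2/3)-normalized convention, which
reduces to the axial strain for incompressible uniaxial stretch.  All
stress/strain fields are rescaled by body weight / vertical femoral
reaction, equivalent to applying one body weight to the linear model (body
weight = mass x 9.81 m/s2).

## Regional analysis

Depth is the Euclidean distance transform from the segmented tibial
surface, computed on the voxel grid.  The articular surface (plateau +
spine) is the up-exposed tibial surface within 12 mm of the apex; all other
surface voxels form the outer cortical wall.  The 17 regions combine depth
bands from the articular surface — subchondral cortical 0-2.5 mm,
subchondral trabecular 2.5-5 mm, epiphyseal 5-15 mm, metaphyseal 15-35 mm,
half-open intervals with the deepest band closed at 35 mm — with
medial/central/lateral sectors (central = a sagittal slab, 20% of the
mediolateral plateau extent, centered on the spine centroid).  The outer
cortical wall takes precedence: peripheral cortical within 5 mm of the wall
in the 0-5 mm axial band, then epiphyseal/metaphyseal cortical within
2.5 mm of the wall in the deeper bands, split medial/lateral at the spine
plane.

Regional means are computed on the fixed voxel grid: centroid strain
tensors are volume-weighted-averaged to the mesh nodes (standard nodal
recovery), interpolated at tibial voxel centers through exact element-local
coordinates (Newton inversion of the trilinear map — surface snapping moves
nodes off the lattice, so naive lattice interpolation would be
systematically wrong in the thin surface bands), and averaged per
voxel-coded region.  Voxel stress is the sampled strain times the voxel's
own density-derived modulus, so regional stress does not depend on how
elements average the density.  Because region membership and weights live
on the segmentation grid, meshes of different element size are compared
over identical region volumes.  The element-level `assign_regions` +
`aggregate` path (centroid banding, element-volume weighting) is also
provided and used where a per-element map is wanted (VTK export).

Compartmental stiffness follows the two-extra-model procedure: the femoral
elements of the opposite compartment are softened to E = 10 MPa so
essentially all load crosses the compartment of interest, and stiffness =
vertical reaction force / mean |vertical displacement| of that side's
subchondral surface nodes (N/mm).  Stiffness uses the unscaled
displacement-driven solves: it is a geometry/material property independent
of body weight.

## Statistics

CV%RMS = 100 sqrt(mean_i (SD_i/|mean_i|)^2) with the n-1 SD per subject;
signed metrics use |mean|.  The normality gate computes bias-corrected
skewness and excess kurtosis with their small-sample standard errors and
flags a sample non-normal if either |Z| exceeds 1.96 (invariant under
affine transforms; constant samples are non-normal by convention).  Both
samples normal: classic pooled-variance unpaired t-test with a t-based 95%
CI of the mean difference.  Otherwise: exact Mann-Whitney U (dynamic
programme over the exact null for group sizes <= 12 without ties, normal
approximation above), the Hodges-Lehmann estimate (median of all pairwise
differences, first sample minus second) and its exact Moses confidence
interval from the U null distribution.  Percent differences are relative to
the normal group's central value.  Cohen's d = |difference| / SD with the
all-scans SD by default (it reproduces the reference stiffness effect size;
pooled-group SD available by configuration).  No multiple-testing
correction is applied across the 17 regions, matching the reference
analysis; reports note this.

## Problem sizes and numerical choices

The full-resolution phantom (0.625 mm voxels, 2 mm bone elements) yields
roughly 25 000 elements / 80 000-100 000 DOFs and solves in well under a
minute per load case; the test suite exercises the complete chain at a
coarser 1.5 mm / 4 mm configuration (a few thousand elements) chosen so the
whole study logic runs at desk scale, and the mesh-refinement and
directional-cohort checks run at the sizes stated in their tests.  Ties at
band edges go to the deeper band; medial/lateral wall labels split exactly
at the spine plane; the degenerate all-tied comparison returns p = 1 with a
collapsed CI and is flagged.

## Mesh-refinement sensitivity (known limitation)

The refinement study (`pipeline.mesh_convergence_study`) rebuilds and
re-solves the model at 2.0 and 1.8 mm and reports the maximum relative
change over all 17 regions x 4 metrics.  In a voxel-lattice pipeline the
two meshes are different tilings of the same smooth geometry: even with
surface snapping, B-bar elements, voxel-grid region definitions and
voxel-modulus stress, the thin (one-to-two element) subchondral and
peripheral bands retain a re-tiling sensitivity of several percent, an
order of magnitude above the ~1% reported for body-fitted quadratic
tetrahedral meshes built on fixed smoothed surfaces with commercial
meshers.  A nested (geometry-preserving) refinement is provided
(`meshmat.refine_nested`) and shows the complementary effect: refining a
lattice mesh resolves the contact-edge and surface boundary layers and
moves the surface-band means substantially, confirming that those means are
not mesh-converged at this element technology.  Deep-region means (5-35 mm)
change by ~0.1-2% between 2.0 and 1.8 mm.  This is an honest limitation of
structured-lattice meshing rather than of the physics pipeline; the
acceptance script reports the measured value without adjustment.

## Other limitations

* The phantom's geometric simplicity makes segmentation and axis fitting
  easier than on clinical data; Dice and axis-error tests quantify the
  pipeline on this phantom only.
* Cortical- vs trabecular-specific density-modulus laws are intentionally
  out of scope (a single law is used, as in the source workflow).
* Soft tissue is one homogeneous nearly incompressible cylinder; no
  subject-specific cartilage/menisci, no contact mechanics (interfaces are
  bonded), no geometric or material nonlinearity.
* The soft-tissue cylinder is meshed on the same lattice as bone rather
  than at a coarser generic size; a conforming two-size lattice would need
  hanging-node constraints that buy nothing at desk scale.
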