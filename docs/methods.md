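# Methods

## Coordinate and unit conventions

All geometry lives in scanner/world millimetres.  A voxel index (i, j, k)
maps to world space as `origin + (i, j, k) * spacing`, voxel-centre
convention, 0-based.  DICOM series and NIfTI volumes must be axis-aligned;
oblique grids are rejected rather than resampled, which keeps the geometry
kernel simple and exact.  STL files carry no units and are read and written
as millimetres.  Internally everything is mm / mm² / mm³; reported values
are cm² and cm³, the conventional clinical units for ostium area and
chamber volume.

## Segmentation

The contrast-enhanced blood pool is separated from background by a single
global threshold.  The automatic initial value is Otsu's
between-class-variance maximum on a 256-bin histogram — the standard
parameter-free choice for bimodal CT contrast.  The threshold is applied
inclusively (intensity ≥ t) and can be overridden, which models the
operator's interactive adjustment in the clinical workflow.  Connected
components use 26-neighbour connectivity: the blood pool is a thick
structure and the fullest connectivity avoids spurious splits at thin
necks.  No morphological cleanup is applied beyond seeded component
selection.

When the two intensity modes are well separated, the between-class
variance is nearly flat across the gap, so the exact threshold within the
gap is arbitrary; only separation matters downstream.

## Surface extraction

Marching cubes at iso-level 0.5 on the {0, 1} mask, padded by one empty
voxel layer so the isosurface always closes.  Laplacian smoothing is
available but off by default because uniform-weight smoothing shrinks
enclosed volume; when enabled, the volume change is logged.

Two discretization facts matter for validation:

- **Volumes converge well.**  The enclosed volume of the binary isosurface
  of a 15 mm sphere at 0.419 × 0.419 × 1 mm is within ~0.5% of the closed
  form.  The smallest instance, one voxel, yields the octahedron through
  the voxel's face midpoints with volume exactly h³/6 — discretization
  dominated, as expected.
- **Areas do not.**  The staircase isosurface of a binary mask
  overestimates surface area by several percent and the bias does not
  vanish with refinement.  Tests therefore validate cropped-surface
  geometry through boundary-circle radii and enclosed volumes, and treat
  absolute mesh areas only as coarse bounds.

## Cropping and the ostium

Interactive freehand cropping is replaced by a plane cut: triangles
crossing the plane are split exactly along it (Sutherland–Hodgman per
triangle, with interpolation points cached per edge so adjacent triangles
share bit-identical vertices), and the connected open submesh on the
seed side is kept.

The ostium cutting plane is fitted to ≥ 3 landmark points: the exact plane
for three, the total-least-squares plane (smallest principal direction of
the centred points) for more.  The ostium contour is the closed plane–mesh
intersection loop, traced by walking triangle adjacency across the plane.
When several loops exist the largest-area loop is taken by default; an
anchor point can override the choice (the pipeline anchors at the ostium
landmark centroid).  The contour area is the shoelace formula in the
plane's orthonormal 2D frame.

Degeneracy policy: vertex–plane distances that vanish exactly are nudged
to +1e-12 mm before any sign test.  Cropping and contour extraction share
this perturbation and the same edge-interpolation routine, so the boundary
of a cropped mesh coincides point-for-point with the intersection contour
— which is exactly what capping requires.

Capping builds a triangle fan from the contour's planar area centroid; if
the polygon is not star-shaped about that centroid (fan would
self-intersect), it falls back to ear-clipping.  The result is checked
watertight and oriented outward by the sign of the divergence-theorem
volume.

## Volumetry

The primary volume is obtained by re-voxelising the closed model at the
source CT resolution and counting interior voxel centres — mirroring the
mask-based definition clinicians use.  Voxel centres lie on a grid aligned
to the model's bounding box with a half-voxel margin plus a fixed
sub-voxel offset (0.0414 × spacing); the offset decorrelates ray positions
from the mesh's own lattice (marching-cubes vertices sit on grid-edge
midpoints) without affecting the expected count.  Interior classification
is +z ray parity; rays that graze an edge or vertex (relative barycentric
coordinate within 1e-9) or return an odd crossing count are re-cast with a
deterministic jitter schedule (up to 8 retries, fixed direction, step
1e-3 × in-plane spacing).  Grids that resolve fewer than 10 interior
voxels trigger a warning — the estimate is then resolution-limited.

The divergence-theorem volume of the same watertight mesh is computed as an
independent second route; the two agree within 2% on smooth phantoms and
serve as mutual checks throughout the tests.  The bounding-box-aligned
grid (rather than the source CT grid) makes the measurement reproducible
without carrying the CT origin; the two choices differ by sub-voxel
sampling only.

## Function and statistics

EF = (max V − min V)/max V on the phase-resolved volume curve; diastole is
the arg-max, systole the arg-min, first occurrence on ties.  Ostium area
and volume can be indexed to body surface area by the Mosteller formula
√(height·weight/3600).

The agreement toolkit follows the standard reproducibility triple:

- **CoV** — within-subject two-rater root-mean-square convention,
  100·√(mean(dᵢ²/2))/grand-mean.  No single canonical formula exists;
  this is the most common in method-agreement work, and the output
  metadata names the convention.
- **Bland–Altman** — bias = mean(d), 95% limits of agreement
  bias ± 1.96·SD(d) with the sample SD (n−1), reported in the open
  interval style `]lo; hi[`.
- **Paired t-test** — two-sided, df = n−1; when every difference is zero
  the result is defined as t = 0, p = 1.

## The phantom

Geometry (defaults, all in mm): an LA sphere of radius 15 centred at the
origin; a neck cylinder of radius 6 along +x from 0.8·R to the junction at
x = 24; a half-ellipsoid appendage body (semiaxes 18 × 14 × 13) distal to
the junction, its radial boundary modulated by cos(3φ) lobes of 1.5 mm
amplitude.  The ostium plane sits at x = 19 with normal +x.  Rendering
uses 0.419 × 0.419 × 1 mm voxels and 10 phases, the native resolution and
phase count of retrospectively gated cardiac CT; blood pool 300,
background 50, additive Gaussian noise of SD 20 (intensity modes must stay
separated by > 3 SD by construction).  The appendage sizes give a
diastolic LAA volume of ≈ 7.5 cm³ and ostium area ≈ 1.1 cm², within the
range seen in adult atrial-fibrillation cohorts.

Contraction multiplies everything distal to the ostium plane by a
per-phase scale s(t) (default profile 1.00 … 0.87 … 1.00) about a point on
that plane, while the LA body stays static.  Because the scaling centre
lies on the plane, the distal volume is exactly s³ × base volume, the
ostium cross-section is exactly s² × π r², and

    EF_truth = 1 − (min s / max s)³  =  0.3415 for the default profile.

The base volume is the analytic neck-cylinder segment plus the lobed
half-ellipsoid integrated by dense indicator sampling at 10× the grid
resolution — independent of all measurement code.  (For zero lobes the
half-ellipsoid volume is the closed form (2/3)πabc; for lobes, a 1D
solid-angle quadrature provides a second independent check in the tests.)

What the phantom does **not** emulate: real LAA morphology classes
(chicken-wing, windsock, cactus, cauliflower), trabeculations, contrast
kinetics, partial-volume blur at the blood–wall interface, or motion
artefacts.  Passing the phantom tests shows the measurement chain is
correct and self-consistent at clinical resolution; it does not establish
clinical accuracy on patient data.  One known phantom artefact: at
scales s < 1 a radius step arises exactly at the ostium plane, so the
measured ostium area at systole is biased a few percent toward the
proximal (unscaled) radius; volumes are unaffected.

## Pipeline conventions

The threshold and landmarks defined on the first phase are reused for all
later phases (operator input is typically needed only once per case);
per-phase overrides are possible by running phases individually.  The
preliminary appendage crop uses the ostium plane shifted 2 mm toward the
atrium, so the final cut at the ostium plane always runs through closed
surface.  Every operator-replaceable decision (threshold, loop selection,
cap method) is recorded in the case report, which makes two-observer
reproducibility studies scriptable: two landmark files are two observers.

Problem sizes used in the validation suite: full-size anatomy at native CT
resolution (≈ 0.6 M voxels per phase, 10 phases) for the end-to-end
parameter-recovery check; 15 mm spheres at the same resolution for the
volumetry oracles; coarser 0.8 mm phantoms for unit tests of the phantom
logic itself.

## Known limitations

- Oblique DICOM/NIfTI geometry is rejected, not resampled.
- The crop is a single plane; anatomies whose ostium is not well
  approximated by a plane would need multiple cuts.
- Simpson's-rule slicing assumes the traced areas are perpendicular to a
  fixed axis with constant slice distance.
- The voxel-counting volume inherits a half-voxel quantisation at flat
  caps; for very small models (≲ 10 interior voxels) it is
  resolution-limited and flagged.
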