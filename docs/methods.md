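# Methods

## Volumes and geometry

A volume is a 3D scalar grid with per-axis spacing (mm), an origin and an
orthonormal direction matrix with determinant +1; voxel `(i,j,k)` sits at
`origin + axes · (index ∘ spacing)` with 0-based indices. Files are read
and written through nibabel (NIfTI-1) and SimpleITK (MetaImage); the
intensities are never rescaled. Headers whose direction matrix is not a
proper rotation are rejected rather than silently reinterpreted — the
segmentation and registration both assume a right-handed frame, and a
flipped axis would silently mirror the anatomy. Mirrored (det = −1)
acquisitions therefore must be reoriented upstream; this is a deliberate
limitation.

## Skin segmentation

Segmentation runs slice by slice along the configured slice axis (default:
third array axis). Per slice, all labels start at 2; background grows from
the below-iso-value corner seeds over 4-connected pixels, labelling
reached sub-threshold pixels 0 and first-contact at/above-threshold pixels
1, whose neighbours are not enqueued. Pixels never reached keep label 2 —
that includes both the body interior and internal air pockets enclosed by
tissue, which is exactly the "body by exclusion" semantics wanted here
(isosurfacing raw intensities would instead carve out lungs and bowel
gas). Pixels exactly at the iso-value count as body edge. 4-connectivity
(not 8) is used so the background cannot leak diagonally through a
1-pixel skin boundary. If every corner of a slice is at/above the
iso-value the slice has no seed and the segmentation raises an error
naming the slice; in-plane padding with the volume's global minimum
(default 1 voxel per border) makes this impossible and also lets the
background flow around objects touching the field of view, such as the
scanner bed. Padding is in-plane only because the algorithm is strictly
2D per slice; the padded border is retained for surface extraction (it
only adds background and does not move the iso-surface).

The implementation is vectorised: the background of a slice is the union
of 4-connected below-threshold components containing a seeded corner
(`scipy.ndimage.label`), and the edge is the set of at/above-threshold
pixels 4-adjacent to that background. This is provably the same fixed
point the queue-based formulation reaches, and the test-suite checks
exact label equality against an explicit FIFO breadth-first oracle on
hundreds of random slices.

Subsampling is pure decimation (keep every factor-th voxel, multiply the
spacing): the robustness of interest is to the raw lower-resolution image,
not to smoothed data. Marching cubes (scikit-image) runs on the {0}→0 /
{1,2}→1 binary mask at level 0.5; vertices are mapped to world mm and the
winding is flipped so triangle orientation and gradient normals agree and
point outward. On an analytic sphere at 1 mm voxels every vertex lies
within half a voxel diagonal (≈ 0.87 mm) of the true radius; the error
scales with the voxel diagonal at coarser resolutions.

## Co-registration

The registration moves the segmented surface X₁ into the frame of the
camera surface X₂ and is rigid throughout — the two surfaces differ in
provenance, connectivity and noise, and a deformable model would
manufacture deformations. Stages:

1. **Front cut.** Vertices whose area-weighted normal makes an angle
   < 90° with the anterior direction (configurable; default +y) are kept,
   with strict inequality at the boundary. Triangles survive only if all
   three vertices do; no clipping or re-meshing, which point-based ICP
   does not need.
2. **PCA orientation.** Principal axes are matched in descending
   eigenvalue order, with per-axis signs chosen by positive dot product
   with the destination axes — valid only under the stated
   consistent-orientation precondition (head-feet, left-right). Nearly
   tied eigenvalues (< 1% relative gap) are rejected as ambiguous; in the
   pipeline this degrades gracefully to the identity-rotation start (see
   multi-start below) rather than failing the run, since a cylindrical or
   spherical patch genuinely has no preferred axes. Because a partial
   camera window and the full segmented front have very different spatial
   extents, the pipeline's PCA compares the camera surface against a
   landmark-centred patch of the front cropped to the camera's own radius;
   with matched extents the initial rotation error drops from tens of
   degrees to a few.
3. **Virtual landmark.** The translation is replaced so the rotated
   segmented-surface landmark lands exactly on the camera-surface
   landmark. Landmarks are snapped to the nearest surface vertex.
4. **Region of interest.** Both surfaces are cropped to a sphere (default
   radius 100 mm) around the camera landmark — the landmark is the only
   guaranteed shared reference, and the crop keeps the optimisation on
   the overlapping anatomy.
5. **Two ICP stages.** Stage 1 untrimmed, stage 2 keeping the 80% of
   correspondences with smallest distance each iteration (trim fraction
   configurable). Trimming by distance is the standard robust reading of
   "refine on the best-matching 80% of the surface".

Three choices matter on smooth, feature-poor skin (abdomen, symmetric
phantoms), and all three were decided by measurement on synthetic ground
truth:

* **Correspondence direction.** Inside the pipeline ICP matches
  camera → segmented: every camera point has a true counterpart on the
  segmented front, while segmented points outside the camera's partial
  coverage do not and would bias the fit by several millimetres. The
  returned transform is inverted back so it still maps X₁ into X₂'s
  frame.
* **Error metric.** The default is point-to-plane against the segmented
  mesh normals, linearised per iteration (Gauss-Newton) with step halving
  so the reported trimmed plane-residual RMS never increases. Plain
  point-to-point ICP slides on dome-like patches and recovered the pose
  in only 3 of 15 trials where point-to-plane recovered 15 of 15 at
  ~0.1°/0.1 mm. The classic closed-form SVD point-to-point update remains
  available (`metric="point_to_point"`, and it is the default of the bare
  `icp` function, whose trimmed Euclidean RMS is monotone by
  construction).
* **Multi-start with RMS arbitration.** The ICP stages run from the PCA
  init and from the identity-rotation init, each with the landmark
  translation as given and with ±15 mm corrections along the landmark's
  tangent plane (10 deterministic branches). The branch with the lowest
  final trimmed point-to-point RMS wins. The tangential starts exist
  because the dominant operator error — a landmark slipped along the
  skin — drags ICP into a nearby local basin that pure iteration cannot
  leave; with them, a 15 mm misplaced landmark changes the recovered
  rotation by under 0.5°.

Defaults: ROI radius 100 mm, trim fraction 0.8, at most 50 iterations per
stage, stop when the trimmed RMS changes by < 1e-4 mm. The whole
registration runs in ~0.3 s on one CPU for a 24k-vertex skin and a
2k-point camera cloud. Applying the result to a volume updates only the
header (origin and direction); voxels are never resampled.

## Error metrics

Hausdorff and per-vertex distances are vertex-to-vertex with a k-d tree
(`scipy.spatial.cKDTree`); point-to-triangle distance would be a strict
refinement but changes nothing about the comparisons made here, which all
use commensurate samplings. The colour map is linear in RGB between blue
(0 mm) and red (capped at 5 mm), rounded to integers, so a 2.5 mm residual
renders as (128, 0, 128). TRE is the mean Euclidean distance between
caller-supplied corresponding landmarks; the usual protocol uses a single
internal target (N = 1). Note that the max of a per-vertex field equals
the directed Hausdorff distance by construction, which the tests exploit.

## Synthetic phantoms

`PhantomSpec` defaults describe an abdomen-scale CT: a 96³ grid of 4 mm
voxels (~38 cm field of view), air at −1000 HU, soft tissue at 40 HU, skin
iso-value −300 HU, Gaussian intensity noise with σ = 20 HU. Bodies are an
ellipsoid, an elliptic cylinder (deliberately symmetric, to exercise the
degenerate-PCA path), or an abdomen-like superellipsoid (in-plane exponent
2.5) with a 15% anterior Gaussian bulge off-centre along the body axis,
which provides the curvature variation a real abdomen has. Noise is
clipped at 99% of the margin between each tissue class and the iso-value,
so no voxel ever crosses the threshold; a σ whose 4σ range exceeds the
margin is rejected. Optional extras: a bed slab spanning the full slice
width (body-intensity by default), and an internal air cavity (a quarter-
scale ellipsoid) that the by-exclusion segmentation must keep inside the
body mask.

The camera simulator cuts the skin front, keeps a contiguous coverage
window around the view apex (coverage fraction of front vertices; tilting
the view rotates the window centre about the body axis), resamples to a
fixed point count (default 2000), adds isotropic Gaussian position noise
and applies the ground-truth pose. The distance-to-noise schedule for the
robustness study is the documented linear stand-in
σ = 0.3 mm + 0.02·distance_cm; real depth-camera noise curves are
hardware-specific. All randomness flows through one seeded generator per
scenario: equal seeds give bit-identical outputs.

What the generator does *not* emulate — and hence what passing tests do
not establish about clinical data: breathing and posture differences
between scan and acquisition, MR intensity inhomogeneity and streak
artefacts, projective depth-camera occlusion and calibration error,
clothing, and anatomy whose front is concave. The phantom study isolates
the algorithmic properties (oracle-exact labelling, surface accuracy at
known resolution, pose recovery under noise/coverage/landmark
perturbations); accuracy on patients additionally depends on the physical
chain the synthetic setup idealises.

## Problem sizes and numerical notes

The test-suite and the acceptance script use the default 96³ phantom
(24k-vertex skin), 2000-point cameras, 50-trial pose-recovery batches and
100-volume oracle batches; these sizes make every property measurable in
seconds while keeping all surfaces well above the resolution scales being
tested. Rotation errors are reported as the angle of the relative
rotation; arccos loses precision near identity, so identity assertions use
a 1e-5-degree floor. ICP arbitration ties are broken by branch order
(PCA before identity, unshifted landmark first), making the pipeline fully
deterministic. Degenerate inputs error early with the stage name: empty
front cuts, empty ROI crops, all-blocked slices, empty/full masks,
fewer than three surviving correspondences.

## Known limitations

* Vertex-to-vertex distances underestimate nothing but can overestimate
  surface distance for sparse samplings; the residual-based warning
  ("> 5 mm on > 10% of ROI vertices") can therefore fire on a perfectly
  registered but sparsely sampled camera cloud.
* The front cut assumes the anterior direction is known per dataset; it
  is configurable but not estimated.
* Mirrored volumes (det −1 direction matrices) are rejected, not fixed.
* The landmark multi-start assumes misplacement up to ~15 mm; grossly
  wrong landmarks (several centimetres) can still anchor the ROI on the
  wrong anatomy.
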