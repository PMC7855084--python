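# Methods

`osteomorph` validates section-based (2D) against volume-based (3D)
morphometry of intracortical bone microstructure on in silico phantoms with
known ground truth: elliptic cylinders standing in for vascular canals and
3:1:1 prolate spheroids standing in for osteocyte lacunae.  This note
records the models, the numerical choices, and what the simulations do and
do not establish about real data.

## Phantom model

### Geometry and rotations

Every phantom is an implicit solid centred in a cubic voxel domain and
rotated by three elemental rotations about the fixed world y-, x- and
z-axes, in that order (extrinsic composition, `R = Rz·Rx·Ry`).  Angles are
drawn independently and uniformly, on [0°, 90°] for randomly oriented
structures and on [0°, 22.5°] for the near-longitudinal "parallel-fibred"
lacuna mode.

*Cylinders* (canals): length 400 units, elliptic cross-section with minor
diameter 10 voxels and major diameter `10 × aspect_ratio`
(aspect ratios 1, 1.25, 1.5, 3), in a 500³ domain.  The unrotated canal
lies **in the transverse plane along y**.  This choice makes the three
rotations play orthogonal roles — the y-rotation spins the elliptic
cross-section about the canal's own axis, the x-rotation sets the
longitudinal angle exactly (ω = rx), and the z-rotation sets the radial
angle exactly (θ = 90° − rz) — so both set angles are uniform on [0°, 90°]
and the expected category mix is ~25% longitudinal, ~19% radial, ~19%
laminar, ~37% oblique, matching the published ground-truth category counts.
(An initial axis along z, the other natural choice, yields only ~5%
longitudinal canals and is irreconcilable with those counts.)

*Ellipsoids* (lacunae): full axes 15 × 5 × 5 µm (set volume
(4/3)π·7.5·2.5² ≈ 196.35 µm³, printed as 196), major axis initially along
z so that parallel-fibred rotations keep lacunae near-longitudinal.  The
same physical lacuna is rendered at nominal voxel sizes 1.6, 0.8 and
0.33 µm by scaling the axes to `full_axes / voxel_size` voxels (exact
division; at 0.33 µm the major axis spans 45.45 voxels) in a 50³ domain.

### Voxelisation and binarisation

Voxels take the fraction of 5³ regularly spaced sub-samples falling inside
the implicit surface ("supersampled occupancy"), which emulates the
partial-volume grey levels of a surface-to-mask conversion.  Voxels
provably interior/exterior — by a Lipschitz bound on the implicit function
evaluated at the voxel centre — skip the sub-sampling, and only the
axis-aligned bounding box of the rotated shape (+2 voxels) is evaluated.

Binarisation uses the minimum-cross-entropy (Li) threshold, minimised
exhaustively over the cut points of a 256-bin histogram; a fixed-point
iteration on the raw values serves as an independent cross-check.
Exactly-zero voxels are excluded from the histogram: a synthetic occupancy
volume has a point mass at 0 where a real CT background has a noise
distribution, and including it makes the cross-entropy minimum degenerate
(threshold → 0, every partial-volume voxel foreground, object sizes
inflated by ~40%).  With the zero bin excluded the threshold lands near
0.4 occupancy and the rendered 196 µm³ lacuna binarises to ≈383 voxels at
0.8 µm, the expected discretisation.

Consequences of partial volume at the coarsest size are physical, not
numerical: at 1.6 µm (≈48-voxel lacunae) boundary voxels dominate and
thresholded counts and fitted volumes overshoot by ~25–30%, as they do in
real coarse-voxel CT; these cells are treated as qualitative.

## Estimators

### 2D (single transverse mid-slice)

Connected regions (8-connected) of the binary mid-slice get the standard
particle-analysis ellipse: same centroid and normalised second central
moments as the pixel region, axes rescaled so the ellipse area equals the
pixel area.  From the full axes a ≥ b:

- longitudinal angle ω = arcsin(b/a) — exact for circular cylinders, where
  the section of a canal tilted to ω is an ellipse with b/a = sin ω;
- radial angle θ = acute angle between the ellipse major axis and the
  bone-surface tangent (the x-axis for phantoms);
- lacunar volume, one section (*xy-plane method*):
  V = (4/3)π r₁ r₂² with r₁ = a/2, r₂ = b/2 (prolate-spheroid model);
- lacunar volume, two perpendicular sections (*xy/xz-plane method*):
  V = (4/3)π r₁ r₂ r₃ with r₂, r₃ from the transverse section and r₁ from
  the major axis of the perpendicular reslice, assuming lacunae align on
  average with the bone's long axis.

2D objects are split into lacunae and canals at 38 µm² (strictly greater =
canal); 3D objects by volume (50–500 µm³ lacunae, >1000 µm³ canals,
500–1000 µm³ excluded, <50 µm³ noise).

### 3D (full volume)

Canals: the binary volume is thinned to a unit-width skeleton
(topology-preserving 3D thinning), voxels are classified by 26-neighbour
count (1 = endpoint, ≥3 = junction), and branches are traced between
nodes.  Each branch is represented by a straight line; its direction is
the total-least-squares line through the branch's path voxels rather than
the difference of the two endpoint coordinates, because half-voxel endpoint
quantisation otherwise dominates θ for near-longitudinal branches.  For the
single-canal cohort pipeline the direction is further refined to sub-voxel
precision: object voxels are binned into unit slabs along the current
direction, each slab is reduced to its transverse centroid (averaging
hundreds of voxels), the outer 5% of slabs is trimmed (oblique end caps
bias their centroids), and the line is re-fitted through the centroids;
two passes converge.  This refinement is what makes θ measurable for
canals within a degree of perfectly longitudinal, whose total transverse
drift is below one voxel.  ω = 90° − angle(direction, bone axis);
θ = acute angle of the transverse projection against the tangent,
undefined when the projection vanishes.

The bone axis is the z-axis for phantoms; for real stacks it is estimated
by fitting a circle to surface points on the first slice and positioning a
same-radius circle on the last slice, the axis joining the two centres.

A robustness note on thinning: the parallel directional thinning
implementation deletes certain perfectly prismatic objects with
even-symmetric cross-sections entirely (they pass through an even-width
square rod, for which every border voxel is removed in one sweep).  A
sub-voxel-tilt cylinder triggers this.  Any connected component left
without skeleton voxels therefore falls back to its rasterised
principal-axis chord, which for those straight tubes is the ideal medial
line.

Lacunae: each component's equivalent ellipsoid is fitted by moment
matching — semi-axes `r_k = sqrt(5 λ_k)` from the covariance eigenvalues
of the voxel centres, the uniform-solid-ellipsoid relation — and
V = (4/3)π r₁ r₂ r₃.  Fits fail (and are excluded but counted) for regions
under 6 voxels or with degenerate moments; at the voxel counts produced
here (≥48) moment fits essentially never fail, so the published ~76%
success rate at 1.6 µm, specific to its fitting tool, is not reproduced
quantitatively.

### Classification and indices

(ω, θ) pairs map to longitudinal (ω > 67.5°), radial (θ > 67.5°), laminar
(θ ≤ 22.5°) or oblique, with upper-inclusive boundaries, ω = 0 admitted,
and θ allowed to be undefined only for longitudinal canals.  Indices are
the category proportions with oblique canals in the denominator only —
count-weighted for 2D data (a section has no canal length), length-weighted
for 3D skeletons.

### Agreement statistics

Pearson r² (pairs with undefined ground-truth θ excluded), mean difference
with the sign convention estimate − reference (so 2D underestimation of ω
is negative), Bland–Altman limits of agreement mean ± 1.96·SD (sample SD,
n−1), and two-tailed Student's t-tests (paired, one-sample, and
pooled-variance two-sample).  Identical paired series define t = 0, p = 1.

## Problem sizes and tolerances

Reproduction runs (test suite and `scripts/acceptance.py`) use 100 phantoms
per condition, as in the study.  Cylinder cohorts run on a half-scale
domain — length 200, domain 250³, diameter 10 voxels unchanged.  The
mid-slice section of a cylinder is determined by its cross-section and
orientation alone, and the sub-voxel direction refinement holds skeleton
angle errors well under the classification boundaries at this length, so
the half-scale statistics match the full-scale ones; full scale remains the
generator default.  Ellipsoid cohorts run at the study's own 50³ scale.

Numerical tolerances: rotation matrices orthonormal to 1e−10; moment
ellipse area preserved to 1e−6 relative; θ undefined below a 1e−9 relative
transverse projection; Li histogram of 256 bins; ellipse fits require ≥3
non-collinear pixels, ellipsoid fits ≥6 voxels with positive-definite
moments.

## What the phantoms do not show

The generator reproduces idealised geometry sliced exactly through each
object's midpoint, with no CT physics: no noise, beam hardening, ring
artefacts, off-centre sections, touching objects, or curved canals.
Passing tests therefore demonstrate properties of the estimators under the
stated geometric assumptions — in particular how 2D section estimates
degrade when cylindricality or alignment assumptions fail — not performance
on real scans.  Known residual limitations:

- θ of canals within ~0.5° of perfectly longitudinal is intrinsically
  ill-conditioned at any finite voxel size; cohort θ-r² values can move by
  a few thousandths depending on whether such a canal is drawn.
- 2D orientation estimates of strongly elliptic canals (1:3) are dominated
  by the random cross-section spin (the mid-slice axis ratio saturates at
  b/a = 1/3 for steep canals), which bounds the attainable ω-r² for that
  cohort near 0.15; see the repository notes for the full analysis.
- The real-data code path (TIFF stacks, bone-axis circle fit, nearest
  tangent) is exercised on phantom stacks only; no experimental CT data
  ships with the package.
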