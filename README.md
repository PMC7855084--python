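# osteomorph

2D versus 3D quantitative morphometry of intracortical bone
microstructure, validated on voxel phantoms with known ground truth.

Bone histology infers three-dimensional traits — the orientation of
vascular canals, the volume of osteocyte lacunae — from two-dimensional
sections by fitting idealised geometries to cross-sections.  Those
inferences rest on strict assumptions (circular canal cross-sections,
lacunae aligned with the bone's long axis) that real tissue rarely
satisfies.  `osteomorph` quantifies exactly how the classical 2D
estimators degrade when the assumptions fail, and how their 3D
counterparts behave on the same objects, by simulating canals (elliptic
cylinders) and lacunae (3:1:1 prolate spheroids) as binarised voxel
volumes with known orientation and volume.  It is aimed at
palaeohistologists and bone-imaging researchers choosing between
section-based and CT-based morphometry.

## The estimators

For a canal with longitudinal angle ω (90° = parallel to the bone's long
axis) and radial angle θ (0° = circumferential/laminar, 90° = radial):

- **2D**: fit the area-preserving second-moment ellipse to the transverse
  mid-slice cross-section; ω = arcsin(b/a) from the full axes a ≥ b, θ =
  acute angle between the major axis and the local bone-surface tangent.
- **3D**: thin the binary volume to a skeleton, trace branches between
  endpoints/junctions, represent each branch by a straight line, and
  measure ω against the bone axis and θ in the transverse plane.

Mean lacunar volume Lc.V̄ is estimated three ways: from one transverse
section as a prolate spheroid, V = (4/3)π r₁ r₂²; from two perpendicular
sections as a triaxial ellipsoid, V = (4/3)π r₁ r₂ r₃; and from the 3D
moment-matched ellipsoid (semi-axes √(5λₖ) from the covariance
eigenvalues).  Canal orientations are classified as longitudinal
(ω > 67.5°), radial (θ > 67.5°) or laminar (θ ≤ 22.5°), and
laminar/longitudinal/radial indices are the category proportions
(count-weighted in 2D, length-weighted in 3D, oblique canals in the
denominator only).

Module map: `phantoms` (geometry, rotations, supersampled voxelisation,
Li threshold, cohorts) · `morpho2d` (sections) · `morpho3d` (skeletons,
ellipsoid fits, bone axis) · `classify` (categories and indices) ·
`stats` (r², Bland–Altman, t-tests, report tables) · `pipeline`/`io`/`cli`
(cohort runs, TIFF/CSV/YAML, command line).  Details and numerical choices
are in `docs/methods.md`.

## Worked example

Measure one randomly oriented elliptic canal with both methods:

```python
import numpy as np
from osteomorph import (CylinderSpec, RotationTriple, voxelise, li_threshold,
                        extract_slices, label_regions_2d, fit_ellipse_moments,
                        omega_from_ellipse, theta_from_ellipse,
                        skeletonise_3d, estimate_canal_direction,
                        branch_angles, estimate_bone_axis, categorise)

spec = CylinderSpec(rotation=RotationTriple(ry=35.0, rx=20.0, rz=10.0),
                    aspect_ratio=3.0, length=200, domain_edge=250)
truth = spec.ground_truth()
binary, _ = li_threshold(voxelise(spec))

xy, _ = extract_slices(binary)
ellipse = fit_ellipse_moments(max(label_regions_2d(xy), key=lambda r: r.area))
w2d = omega_from_ellipse(ellipse.a, ellipse.b)
t2d = theta_from_ellipse(ellipse.phi)

direction = estimate_canal_direction(binary)
w3d, t3d = branch_angles(direction, estimate_bone_axis(phantom=True))

print(f"set:  omega={truth.omega_true:.1f}  theta={truth.theta_true:.1f}")
print(f"2D:   omega={w2d:.1f}  theta={t2d:.1f}  -> {categorise(w2d, t2d)}")
print(f"3D:   omega={w3d:.1f}  theta={t3d:.1f}  -> {categorise(w3d, t3d)}")
```

prints

```
set:  omega=20.0  theta=80.0
2D:   omega=14.5  theta=79.4  -> radial
3D:   omega=20.0  theta=80.0  -> radial
```

The set angles follow directly from the rotation draw (ω = rx,
θ = 90 − rz).  The 3D skeleton recovers both angles to 0.1°, while the 2D
section — whose shape mixes the canal's tilt with its 1:3 elliptic
cross-section — underestimates ω by 5.5°.  Here the canal still lands in
the right category; averaged over random cross-section spins the same
confusion collapses the correlation between set and 2D-estimated angles
(r² ≈ 0.1 at this aspect ratio) and misclassifies every
ground-truth-longitudinal canal, which is the central failure mode of
section-based orientation estimates for non-circular canals.

Cohort-scale runs come from the pipeline, e.g.

```bash
osteomorph full-run --config examples/config.yaml --out results/
```

with a YAML config listing cohorts (kind, aspect ratio or voxel size,
alignment mode, n, seed; see `examples/config.yaml`); it writes per-phantom CSVs plus the
orientation-agreement, classification-accuracy and lacunar-volume summary
tables.  `osteomorph generate / analyse-2d / analyse-3d / classify /
report` expose the individual stages for TIFF stacks.

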