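# Methods

This note records the model, the numerical choices and the limits of
what the synthetic studies can show. Angles are degrees, lengths mm.

## Geometry

The world frame sits at the isocenter. The untilted orbit revolves
about `orbit_axis` (+z, patient cranio-caudal); the tilt rotates the
whole rig — source circle, detector and detector axes — rigidly by
`delta` about `tilt_axis` (+x, patient left–right), so the orbital
angle `theta'` is measured within the tilted plane. At
`theta' = 0, delta = 0` the source lies on −y (anterior–posterior).
Projection matrices are standard pinhole: `P = K [R | -R s]` with the
camera rows being the detector column, detector row and central-ray
directions, focal length = source–detector distance, principal point =
detector center `(cols/2, rows/2)` in continuous pixel coordinates
(pixel `(i, j)` has center `(i+0.5, j+0.5)`). Back-projection uses the
matrix pseudo-inverse and the null-space camera center only, so
externally calibrated scout poses imported from the plain-text matrix
format behave identically to constructed ones.

Default system: source–isocenter 622 mm, source–detector 1164 mm,
400×400 detector at 1 mm pitch, `theta' ∈ [−100°, 100°]` at 1° (a
200°-arc short scan), `delta ∈ [−30°, 30°]` at 1°. These are
conventional mobile-C-arm values; every one is configurable and none
is hard-coded in an algorithm.

## Triangulation

`closest_point_between_rays` returns the *unconstrained* line–line
closest midpoint and gap together with both ray parameters; the
forward-half-line requirement (closest approach in front of both
sources) is enforced as an admissibility gate during matching, not as
a clamp in the primitive — back-intersections are physically
meaningless matches, but the primitive itself stays the exact
least-squares solution. A cross-view object pair is admissible when
head-ray and tip-ray gaps are each ≤ 5 mm (configurable) and forward;
among admissible pairs a rectangular assignment minimizing
`head_gap + tip_gap` (scipy's Hungarian solver) yields a deterministic
one-to-one matching. Head and tip are triangulated independently and
paired by per-view object identity; there is no joint refinement and
no epipolar-guided detection.

## Ellipsoid surrogates

`Sigma`'s eigenvalues are squared *semi*-axes. The fitted major full
axis equals the head–tip distance; "minor axes of 5 mm" is read as a
*diameter* (semi-axis 2.5 mm), the only reading consistent with screw
diameters of 4–7.5 mm; `minor_full_axis_mm` is configurable, and the
synthetic module can instead use each screw's true diameter. Sigma is
stored as a full symmetric matrix, symmetrized at construction with a
1e-9 asymmetry guard, positive-definiteness checked by
eigendecomposition, and semi-axes bounded by 200 mm as a sanity limit
for surgical scenes. The tulip-shaped screw head is deliberately not
modelled; against segmentation-style baselines this shows up as the
surrogate under-reporting the longest paths by roughly the tulip size.

## Scoring

`ray_path_length` solves the ray–quadric intersection exactly and
clips to the forward half-line; a miss or tangency returns 0. The
analytic scorer exploits that the chord through the centroid,
`2 / sqrt(d^T Sigma^-1 d)`, dominates all parallel rays, so per pose it
evaluates one chord per object along the source→centroid direction and
takes the per-object maximum. Overlap between objects is *ignored by
design* (max, not sum, over objects); `q_atten_summed` exists as a
diagnostic to quantify that assumption.

Field-of-view semantics differ between scorers and are intentional:
the analytic scorer evaluates the centroid chord whether or not the
centroid projects onto the physical detector (the metric's definition
has no field-of-view test), while the rendered and voxel scorers are
detector-limited. Oracle comparisons therefore restrict themselves to
poses where every silhouette lies on the detector; the silhouette is
obtained in closed form from the projected dual quadric
(`C* = P Q* P^T`), whose axis-aligned tangents give exact pixel
bounds. The rendered scorer samples only that bounding box (clipped to
the detector, on a lattice aligned to a global grid), which preserves
the maximum exactly while keeping ray counts proportional to
silhouette area; `render_path_length_image` renders full frames with
integer pixel strides for image-level uses.

The voxel baseline marks a voxel occupied when its center is inside
any ellipsoid (grid = bounding boxes + 2 mm padding) and accumulates
exact radiological paths with an Amanatides–Woo traversal (numba JIT
when available; a vectorized sorted-plane-crossing fallback otherwise
— both agree to 1e-11). Candidate rays are prefiltered by projecting
coarse 8³-voxel occupied blocks, which cannot discard a ray that
intersects metal. Default sampling is 1 mm pixels and 1 mm voxels.

Cost is *counted*, not timed: the analytic metric map performs exactly
`M × |theta grid| × |delta grid|` chord evaluations independent of
detector resolution, while rendered/voxel ray counts scale with
sampled pixel area — the mechanism behind the method's speed.

## Tilt selection

`Q_atten(delta) = max_theta' q_atten(theta', delta)`;
`threshold = q_max − fraction·(q_max − q_min)` with `fraction = 0.95`
by default; among grid tilts with `Q ≤ threshold` the
smallest-magnitude one wins, ties break toward positive tilt, and a
flat curve selects the grid tilt nearest 0 (the standard untilted
orbit). `fraction = 1` recovers the plain argmin. `delta*` is
restricted to the evaluated grid — candidate trajectories are
discrete; no interpolation. A guard re-admits the exact argmin if
floating-point rounding pushes the threshold below `q_min`.

The maximizing pose of a metric map need not be unique: scenes with
several similar screws produce numerically tied maxima (within ~0.05%)
at distant poses, and near-symmetric implant layouts give
mirror-degenerate `Q(delta)` curves whose selected tilt sign can flip
under tiny perturbations. Comparisons of maxima *locations* across
scorers are therefore made up to numerical ties; value agreement is
asserted pose-by-pose.

## Synthetic scenes and observations

Scenes emulate pedicle-screw scenes: lengths uniform in 35–65 mm,
diameters uniform in 4–7.5 mm, inside a ±70 mm box around the
isocenter (a lumbar-sized surgical field that also keeps silhouettes
on the default detector), pairwise centroid separation ≥ 20 mm. Sizes
and orientations are drawn first and the centroid is then uniform over
the sub-box where the screw fits, with rejection (on the centroid
alone) enforcing separation — this keeps length, diameter and
orientation marginals exactly uniform, which whole-screw rejection
would bias. Orientations are uniform on the sphere by default; the
`clinical` preset confines axes to a 30° cone about the
anterior–posterior direction (pedicle-like trajectories), and
`generate_paired_scene` arranges bilateral pairs per vertebral level
along the orbit axis to mimic L1–L4 instrumentation.

Observations emulate a 2D keypoint detector: projected head/tip pixels
with isotropic Gaussian noise, whole-object per-view dropout, spurious
head/tip *pairs* uniform on the detector (pairs, so they exercise the
matching gate), and per-view identity shuffling so correspondence is
genuinely unknown. Not emulated: anatomy-dependent detection failure,
correlated localization error, image content of any kind, and
non-screw metal — so passing tests show the geometry and matching
machinery is correct under the stated noise model, not that a real
detector meets these error levels on clinical images.

## Study conditions behind the validation numbers

* Oracle agreement: 25–50 random scenes of 1–8 screws, candidate grid
  at 10°/6° steps, rendered oracle at 0.5 mm sampling, in-field poses;
  observed worst per-pose disagreement ~0.25% (tolerance 2%).
* Cross-method tilt agreement: pedicle-like (`clinical`) 6-screw
  scenes, 10°/5° grids, 1 mm voxels and pixels. Isotropically oriented
  scenes are *not* used here: the parametric method assumes screw major
  axes are well separated, and isotropic scenes violate it — multi-
  screw ray overlap inflates the voxel baseline's curve asymmetrically
  and can flip the selected tilt across the grid. The acceptance script
  additionally reports the regret of the analytic choice measured on
  the voxel curve, which stays at the few-mm level even when the
  discrete tilt choices differ.
* Triangulation: noiseless recovery < 1e-6 mm over 100 scenes; with
  1 px noise, ≥ 99% correct correspondences and ≥ 95% of centroids
  within 2 mm over 200 scenes.
* Grid resolutions in tests and the acceptance script are coarser than
  the 1° defaults; they are the package's chosen desk-scale study
  sizes, and every result above is independent of that choice in the
  regimes tested.

## Known limitations

* The ellipsoid ignores the tulip head and thread geometry; composite
  multi-primitive implants are out of scope.
* Overlapping projections are not summed; scenes with near-collinear
  screws under-estimate the true worst path.
* The analytic score has no field-of-view test; trajectory grids whose
  implants leave the detector mix semantics between scorers.
* Two views only, one detector per view, no bundle adjustment, no
  learned correspondence; dense implant fields with many mutual
  epipolar near-misses will drop or mis-match objects.
* Convergence of the finite-focus score to the parallel-beam chord is
  first order in (scene radius / source–isocenter distance); claims of
  exact equality hold only for spheres.
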