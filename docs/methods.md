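# Methods

This note documents the models, numerical choices and known limitations
of `endosize`.  It is written for users who want to understand what the
measurements mean, what the synthetic experiments do and do not show, and
where the genuinely open design choices were made.

## Measurement model

The polyp is modelled as a planar region whose border, reconstructed in
3D, is summarized by a least-squares ellipse: the full major-axis length
is the reported size, the ellipse-centre z coordinate in the **first**
camera's frame is the reported depth (the convention had to be fixed; the
first image is the one that was segmented).  This planar-ellipse model is
the measurement model itself, not an approximation added here: raised
(hemispherical) polyps violate it, and the simulator's optional raised
mode is deliberately excluded from validation.

All lengths are millimetres.  The camera frame has +z along the optical
axis, +x right, +y down; pixels are 0-based with the origin at the
top-left corner.  A `RigidTransform` carries explicit `from_frame` /
`to_frame` labels (generator, sensor, camera, pattern, scene) and
composition validates them — frame bugs surface as errors, not as wrong
numbers.

### Sensor convention

The EM tracker reports position plus azimuth/elevation/roll.  These are
interpreted as intrinsic Z–Y–X Euler angles (the native convention of the
tracker family this targets).  The convention is a documented choice, not
a certainty about any particular device, which is why
`sensor_to_transform` is the single point where it is applied.

### Hand-eye direction

Both directions of the sensor↔camera transform appear in the literature
under the same symbol.  Here one canonical direction is used everywhere:
the stored hand-eye transform maps **sensor-frame coordinates into the
camera frame** and is exactly the `X` that satisfies `A X = X B` for
camera motions `A = cTp_i · cTp_j⁻¹` and sensor motions
`B = gTs_i⁻¹ · gTs_j`.  The relative camera pose is then
`X · gTs1⁻¹ · gTs2 · X⁻¹` and the camera→generator chain is
`gTs · X⁻¹`.  The construction-oracle tests pin this algebra down.

### Hand-eye solver

The rotation equation `R_a R = R R_b` is linearized row-major as
`(I9 − R_a ⊗ R_b) vec(R) = 0` (this is the stacking convention under
which that Kronecker form is exact; a self-consistency test re-substitutes
the solved vector and reproduces the reported residual to 1e-12).  After
the joint linear solve the 3×3 block is projected to the nearest rotation
by SVD (det +1 enforced) and the translation re-estimated with the
rotation fixed — the joint solution's translation otherwise inherits the
un-orthonormalized rotation's error.  Parallel rotation axes leave the
translation along the common axis unobservable; the solver refuses motion
sets whose axes all agree within 1° (sign-invariant axis comparison).

Pose selection implements the two after-the-fact capture heuristics:
discard motions rotating less than `min_angle_deg` (default 5°), then
greedily maximize the minimum pairwise angle between rotation axes,
breaking ties by rotation magnitude.

### Intrinsics

Planar-target calibration: normalized-DLT homographies per view, the
closed-form intrinsics from the stacked homography constraints, extrinsics
from each homography, then a joint Levenberg–Marquardt refinement of
intrinsics + distortion (k1, k2, k3, p1, p2) + per-view poses with a
block-sparse Jacobian.  On noiseless synthetic corners the recovery is
exact to numerical precision (reprojection RMSE ~1e-12 px).

Checkerboard corners are found from the Harris response, ordered by
growing an integer lattice outward from a central seed (linear
extrapolation from assigned neighbours tracks perspective drift), and the
inner-corner window plus its orientation is selected by the alternating
black/white saddle contrast around each corner — this also resolves the
grid's 180° and mirror ambiguities and rejects placements offset onto the
board outline.  The "8 × 9" board is interpreted as the inner-corner
grid; both counts and the square size are parameters.

### Distortion

Brown model (radial k1–k3, tangential p1–p2).  Inversion is fixed-point
iteration in normalized coordinates, max 20 iterations, tolerance 1e-8;
round-trip error is below 1e-6 px across the field of view for the
barrel-dominant distortions of wide-angle endoscope optics.

### Segmentation

Canny on the V channel of HSV, morphological closing (disc r=5), hole
filling, then an opening (disc r=7) that prunes thin protrusions —
protrusions are nearly invisible in Dice terms but directly inflate the
fitted major axis.  Components are filtered by area (0.2–60% of the
image) and eccentricity (≤ 0.85); the least eccentric candidate wins,
ties by area.  Canny hysteresis thresholds are expressed as quantiles of
the per-image gradient distribution (defaults 0.95/0.99) so that the same
defaults survive contrast stretching; absolute thresholds are available
by switching `canny_quantiles` off.  When nothing passes the filters the
result says so (`found=False`) rather than raising, so a pipeline can
fall back to a manual ROI (polygon/mask input is supported).

Mask degradation for sensitivity studies (`perturb_mask_to_dsc`) models a
hand-drawn boundary: a smooth random jitter field (correlation length
0.08 of the equivalent radius, amplitude 0.8·(1−DSC)·r_eq) plus a uniform
signed offset found by bisection on the signed distance transform so the
Dice coefficient lands within 0.01 of the target.  Fine-scale jitter is
deliberate: it spends part of the Dice budget on irregularity that the
ellipse fit averages out, as manual outlines do, instead of attributing
the entire deficit to a systematic over/under bias.

### Tracking and border transfer

Features (SIFT by default, ORB fallback) are detected inside the ROI
dilated by a 30 px margin and tracked by a pyramidal Lucas–Kanade tracker
(3 levels, 21 px windows) written on `scipy.ndimage` primitives.  The
pyramid is seeded with the global inter-frame shift from phase
correlation — endoscope wiggle between captures routinely exceeds a small
pyramid's native capture range.  Tracks are kept only if the
forward–backward error is ≤ 1 px and the window normalized
cross-correlation after convergence is ≥ 0.5 (the NCC gate removes the
spurious self-consistent tracks that survive pure geometric checks on
uncorrelated content).

Epipolar filtering uses the essential matrix of the *tracker-derived*
relative pose and a 2 px Sampson gate.  Under full tracker noise the
predicted epipolar geometry itself can be off by a few pixels, which
rejects genuine matches wholesale; if fewer than half the matches (or 8,
whichever is larger) survive, the pipeline falls back to the unfiltered
set and flags the measurement (`epipolar_fallback`).

The border is transferred with a 2D **affine** map fitted to the matches
(random-sample consensus at 3 px, least-squares refit on the consensus
set).  The affine model is the method's stated choice even though two
views of a plane are related by a homography; its adequacy is therefore a
*measured* property, not an assumption.  The misfit is first order in the
inter-view rotation and quadratic in field position: it vanishes for
rotation-free lateral motion and costs roughly 0.06% of size per degree
of rotation at 26.7 mm depth in the simulated geometry.  This is exactly
why near-static and purely axial movements fail (tiny baselines amplify
any transfer error in triangulation) and why lateral, small-rotation
movements are the recommended capture technique.

### Triangulation and ellipse fit

Linear two-view triangulation per point, solved in normalized camera
coordinates (which provides the conditioning that pixel-coordinate
implementations obtain from Hartley normalization); a midpoint-method
alternative is kept behind a flag for cross-checks.  Points reconstructed
behind either camera are excluded (cheirality).  Baselines below 0.5 mm
are refused with an explicit "insufficient baseline" error instead of
returning a wildly wrong number.

The 3D border is centred, the plane taken from the principal axes, and
the in-plane conic fitted by the direct least-squares ellipse method
(scikit-image's `EllipseModel`).  If the conic degenerates, the
minimum-area enclosing ellipse (Khachiyan's algorithm) is used and the
result flagged so downstream statistics can exclude it.

### Aggregation and metrics

Approach A reports the first pair.  Approach B requires the six pair
estimates of a four-image capture, removes exactly one minimum and one
maximum (stable index order — ties do not remove duplicates) and averages
the remaining four; the same rule applies to depth and to each location
component.  Summary statistics use the sample SD (n−1);
CoV = 100·SD/mean; relative error = 100·|est − actual|/actual.

## The simulator

The simulator emulates a bench phantom study: a flat disc polyp (default
diameter 10 mm) on a procedurally textured plane, viewed by a wide-angle
camera (480×480 px, f = 300 px, barrel distortion k1 = −0.18, k2 = 0.03)
rigidly coupled to a 6DoF sensor through a fixed hand-eye transform, with
a simulated Z-line landmark 223.57 mm away.  Observation modes:

- **correspondence** — exact projected border and feature-point
  correspondences (optionally with pixel noise), bypassing pixel
  processing for geometry-only experiments;
- **image** — shaded disc over band-limited procedural texture rendered
  through the full camera model by per-pixel inverse mapping, with
  ground-truth mask and border.

Sensor noise: per-axis position noise σ_t/√3 (so the 3D position RMSE is
σ_t, default 0.73 mm) and a rotation about a uniformly random axis by
|N(0, σ_r)| degrees (default 0.61°) — both defaults are the tracker
accuracies measured on a positioning grid in the target environment.
Correspondence pixel noise defaults to 0.5 px and is applied to feature
matches only; the border in image 1 plays the role of the segmentation
and is perturbed through the mask tools instead.  A distance-to-source
noise dependence is supported only as a user-supplied multiplier
(`NoiseSpec.scaled`), since no functional form is available.

Movement-type sampling follows a six-way taxonomy of the relative camera
motion (displacement < 3 mm → type 0; otherwise split on depth change
< 2 mm along the first camera's optical axis and on rotation magnitude at
5° and 20°).  "Depth change" is camera-axis translation, the reading
adopted here of an ambiguous notion.  The sampler draws a lateral drift
of 0.38–0.60 of the viewing depth (an operator keeping the polyp in a
wide field of view), a small re-aim rotation for the favourable types
(0.5–6° for type 1, 6–18° for type 4), larger pans (21–28°) for types 2
and 5, axial moves of 4–12 mm for types 3–5, and rejection-samples until
the pair classifies to the requested type with the polyp fully in frame.
The small type-1 rotations are a deliberate modelling choice: the affine
border transfer is exact for rotation-free lateral motion, and the
favourable-movement capture technique this tool recommends is precisely
"translate, don't re-aim".

What the simulator does **not** model: raised polyp relief, specular
highlights, bubbles and occlusions, tissue deformation and peristalsis
between captures, and any distance-dependence of tracker noise.  Passing
the synthetic suites therefore demonstrates the geometric correctness and
noise behaviour of the chain, not robustness to real endoscopic imagery.

## Problem sizes in the validation suites

The simulation experiments use 50 pairs per movement type (types 1–2,
depths 25–40 mm), 20 pairs per depth on the {25,30,…,55} mm grid, and 20
degraded masks (10 over-, 10 under-segmented) at Dice 0.90; the
aggregation comparison uses 50 four-image repetitions.  Under those
conditions the mean size error is ~4–5% for types 1–2 under full tracker
noise, below 6% at every depth grid point, ~9% at Dice 0.90, and a
noiseless type-1 pair at 26.7 mm measures within ~0.2%.  All suites are
seeded and deterministic.

## Known limitations

- The affine transfer bounds achievable accuracy once the inter-view
  rotation grows; above ~20° (types 2 and 5) the noiseless floor is
  ~0.5–1% rather than ~0.1%.
- Size accuracy degrades as the baseline shrinks; type-0/3 movements are
  refused (zero baseline) or measured poorly (small lateral baseline) by
  design.
- Segmentation constants target the rendered phantom appearance; real
  endoscopic images (moisture, highlights, vignetting) will need the
  manual-ROI fallback more often.
- The Z-line location uses the sensor origin at the moment the landmark
  is passed; a fixed tip-offset vector can be configured but no offset
  calibration is provided.
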