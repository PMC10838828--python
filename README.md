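# endosize

Quantitative measurement of gastrointestinal polyp size and location from
tracked endoscopy.

Polyp size drives clinical decisions — resect or survey, and at what
interval — yet visual size estimation during endoscopy is notoriously
unreliable. `endosize` implements a measurement chain for an endoscope
fitted with a 6DoF electromagnetic (EM) sensor: two (or four) endoscopic
images of the polyp are captured together with the synchronized sensor
poses, and the polyp's true metric size and its distance from an
anatomical landmark (the Z line at the gastroesophageal junction) are
computed from image geometry alone — no graduated tool, no laser, no
learning-based sizing.

## Method

Two offline calibrations are required once per endoscope:

1. **Camera calibration.** Planar-target (checkerboard) calibration of the
   pinhole intrinsics `K` and Brown radial/tangential distortion.
2. **Hand-eye calibration.** The fixed transform `X` between the EM sensor
   and the camera solves `A X = X B`, where `A` is the camera motion
   between two checkerboard views (from extrinsics) and `B` the sensor
   motion (from tracker readings).  Writing the rotation part row-major,
   each motion *i* contributes the homogeneous block

   ```
   [ I9 − R_ai ⊗ R_bi      0     ] [vec(R)]   [ 0   ]
   [ I3 ⊗ t_biᵀ        I3 − R_ai ] [  t   ] = [ t_ai]
   ```

   and the stacked system is solved by linear least squares, with the 3×3
   block projected onto SO(3).  Pose-selection heuristics (spread rotation
   axes, large rotation angles) are provided.

Per measurement, for an image pair with sensor readings `s1, s2`:

- segment the polyp border in image 1 (Canny on the HSV V channel +
  morphology + eccentricity/area shape selection);
- detect features (SIFT) in a margin around the border, track them into
  image 2 with pyramidal Lucas–Kanade, reject epipolar outliers using the
  essential matrix implied by the tracked relative pose
  `T_rel = X · T(s1)⁻¹ · T(s2) · X⁻¹`;
- fit a robust 2D affine map to the surviving matches and transfer every
  border point into image 2;
- triangulate the border correspondences (linear two-view DLT), fit a 3D
  planar ellipse to the reconstructed border: the **major-axis length is
  the polyp size**, the ellipse-centre z is the **depth**, and mapping the
  centre through `T(s1) · X⁻¹` gives the position in the tracker frame,
  hence the distance to the recorded Z-line landmark.

With four images, all six pairs are measured and the final estimate drops
one minimum and one maximum and averages the remaining four (approach B);
approach A uses the first pair only.

A synthetic tracked-endoscopy simulator (disc polyp on a textured plane,
wide-angle distorted camera, six-type movement taxonomy, tracker noise at
configurable magnitudes) provides exact ground truth for every stage.

## Worked example

```python
import numpy as np
from endosize import (Calibration, NoiseSpec, make_scene, measure_pair,
                      relative_error)
from endosize.simulator import make_observation_pair, sample_pose_pair

scene = make_scene(seed=1)                       # 10 mm polyp
p1, p2 = sample_pose_pair(scene, movement_type=1, depth_mm=26.7, seed=102)
obs1, obs2 = make_observation_pair(scene, p1, p2,
                                   noise=NoiseSpec(0.73, 0.61, 0.5), seed=5)
calib = Calibration(scene.camera, scene.hand_eye)
m = measure_pair(obs1, obs2, calib)
print(f"size  {m.size_mm:.2f} mm")
print(f"depth {m.depth_mm:.2f} mm")
print(f"error {relative_error(m.size_mm, scene.polyp_diameter_mm):.2f} %")
```

prints

```
size  10.32 mm
depth 26.97 mm
error 3.24 %
```

— the 10 mm polyp measured from one image pair at ~26.7 mm viewing depth
under tracker noise of 0.73 mm / 0.61° RMSE and 0.5 px correspondence
noise.  Without noise the same pair measures to ≪ 0.4 %.

A command-line interface mirrors the library:
`endosize simulate`, `endosize calibrate-intrinsics`,
`endosize calibrate-handeye`, `endosize measure`, `endosize evaluate`
(sensitivity sweeps over movement type, depth, segmentation quality and
noise scale, written as CSV + box plots).

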