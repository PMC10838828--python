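"""Synthetic tracked-endoscopy data with exact ground truth.

The simulator emulates the phantom bench setup the method is designed
for: a flat disc "polyp" of known diameter lying on a textured plane
(the mucosa), a wide-angle distorted endoscope camera whose pose between
the two captures of a pair follows a six-type movement taxonomy, a 6DoF
electromagnetic sensor rigidly mounted to the camera through a fixed
hand-eye transform, and tracker noise at configurable translation /
rotation magnitudes.

Two observation modes are provided:

``image``
    A shaded disc over a procedurally textured plane rendered through the
    full camera model (with lens distortion), plus the ground-truth mask
    and border polygon — exercises segmentation, feature detection and
    tracking.
``correspondence``
    The exactly projected border polygon and feature-point
    correspondences, bypassing pixel processing for geometry-only tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .geometry import (
    CameraModel,
    RigidTransform,
    SensorReading,
    compose,
    invert,
    project,
    rotation_angle,
    sensor_to_transform,
    transform_to_sensor,
)

__all__ = [
    "SceneConfig",
    "Scene",
    "NoiseSpec",
    "Observation",
    "make_scene",
    "classify_movement",
    "sample_pose_pair",
    "sample_pose_set",
    "render_observation",
    "make_observation_pair",
    "add_sensor_noise",
]

#: Movement-type bounds (mm / degrees) of the six-way taxonomy.
MIN_DISPLACEMENT_MM = 3.0
DEPTH_CHANGE_MM = 2.0
SMALL_ROT_DEG = 5.0
LARGE_ROT_DEG = 20.0


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor and correspondence noise magnitudes.

    ``sigma_t`` is the 3D position RMSE in mm (split per axis as
    sigma_t/sqrt(3)); ``sigma_r`` the rotation-angle noise scale in
    degrees (half-normal rotation about a random axis); ``sigma_px`` the
    isotropic pixel noise added to feature correspondences.
    """

    sigma_t: float = 0.73
    sigma_r: float = 0.61
    sigma_px: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_t, self.sigma_r, self.sigma_px) < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def scaled(self, factor: float) -> "NoiseSpec":
        """Uniformly scaled noise (proxy for e.g. source-distance effects)."""
        return replace(self, sigma_t=self.sigma_t * factor,
                       sigma_r=self.sigma_r * factor,
                       sigma_px=self.sigma_px * factor)

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(sigma_t=0.0, sigma_r=0.0, sigma_px=0.0)


@dataclass(frozen=True)
class SceneConfig:
    polyp_diameter_mm: float = 10.0
    landmark_distance_mm: float = 223.57
    n_border_points: int = 144
    n_feature_points: int = 90
    image_width: int = 480
    image_height: int = 480
    fx: float = 300.0
    k1: float = -0.18
    k2: float = 0.03

    def __post_init__(self):
        if self.polyp_diameter_mm <= 0:
            raise ValueError("polyp diameter must be positive")


@dataclass
class Scene:
    camera: CameraModel
    hand_eye: RigidTransform           # sensor frame -> camera frame
    polyp_center: np.ndarray           # generator frame, mm
    polyp_normal: np.ndarray           # unit
    polyp_diameter_mm: float
    plane_e1: np.ndarray               # in-plane orthonormal basis
    plane_e2: np.ndarray
    landmark_position: np.ndarray      # simulated Z-line, generator frame
    border_points_3d: np.ndarray       # (N, 3) exact disc boundary
    feature_points_3d: np.ndarray      # (M, 3) trackable points on the plane
    texture_seed: int = 0

    @property
    def polyp_radius_mm(self) -> float:
        return self.polyp_diameter_mm / 2.0


@dataclass
class Observation:
    """One capture: synchronized sensor reading plus image-plane data.

    ``border_px`` / ``feature_px`` are distorted pixel coordinates (what a
    real camera would deliver); ground truth needed for evaluation rides
    along in ``true_pose`` (the camera pose ``^g^T_c``) and
    ``true_sensor``.
    """

    sensor: SensorReading
    border_px: np.ndarray | None = None
    feature_px: np.ndarray | None = None
    image: np.ndarray | None = None
    mask: np.ndarray | None = None
    true_pose: RigidTransform | None = None
    true_sensor: SensorReading | None = None
    frame_id: int = 0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, n)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(a, n))
    return e1, np.cross(n, e1)


def make_scene(config: SceneConfig = SceneConfig(), seed: int = 0) -> Scene:
    """Build a deterministic scene from a config and a seed."""
    rng = np.random.default_rng(seed)
    cfg = config
    cam = CameraModel(
        fx=cfg.fx, fy=cfg.fx,
        cx=(cfg.image_width - 1) / 2.0, cy=(cfg.image_height - 1) / 2.0,
        k1=cfg.k1, k2=cfg.k2,
        width=cfg.image_width, height=cfg.image_height,
    )
    # polyp somewhere in the working volume of the field generator
    center = np.array([40.0, -25.0, 180.0]) + rng.uniform(-15, 15, 3)
    normal = _unit(np.array([0.15, -0.1, -1.0]) + rng.normal(0, 0.08, 3))
    e1, e2 = _orthonormal_basis(normal)

    r = cfg.polyp_diameter_mm / 2.0
    th = np.linspace(0.0, 2 * np.pi, cfg.n_border_points, endpoint=False)
    border = center + r * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2))

    # trackable plane points spread from on-polyp out to the margin region
    rad = r * np.sqrt(rng.uniform(0.3 ** 2, 1.55 ** 2, cfg.n_feature_points))
    ang = rng.uniform(0, 2 * np.pi, cfg.n_feature_points)
    feats = center + (rad * np.cos(ang))[:, None] * e1 \
        + (rad * np.sin(ang))[:, None] * e2

    # fixed sensor mount: a few mm offset, a modest fixed tilt
    he_rot = Rotation.from_rotvec(rng.normal(0, 0.25, 3)).as_matrix()
    he_t = np.array([4.0, 6.0, -14.0]) + rng.uniform(-2, 2, 3)
    hand_eye = RigidTransform(he_rot, he_t, from_frame="sensor",
                              to_frame="camera")

    lm_dir = _unit(np.array([-0.3, 0.4, -0.85]) + rng.normal(0, 0.05, 3))
    landmark = center + cfg.landmark_distance_mm * lm_dir
    return Scene(
        camera=cam, hand_eye=hand_eye, polyp_center=center,
        polyp_normal=normal, polyp_diameter_mm=cfg.polyp_diameter_mm,
        plane_e1=e1, plane_e2=e2, landmark_position=landmark,
        border_points_3d=border, feature_points_3d=feats,
        texture_seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


# ---------------------------------------------------------------------------
# movement taxonomy
# ---------------------------------------------------------------------------

def classify_movement(pose1: RigidTransform, pose2: RigidTransform) -> int:
    """Movement type 0..5 of the relative camera motion between two poses.

    Type 0: displacement < 3 mm (regardless of rotation).  Otherwise the
    split is on depth change along the first camera's optical axis
    (< 2 mm: types 1/2 by rotation below/above 20 deg) and on rotation
    magnitude for depth-changing moves (type 3 < 5 deg, type 4 in
    [5, 20] deg, type 5 > 20 deg).
    """
    rel = compose(invert(pose1.relabel("camera", "generator")),
                  pose2.relabel("camera", "generator"))
    displacement = float(np.linalg.norm(rel.translation))
    depth_change = abs(float(rel.translation[2]))
    rot = rotation_angle(rel)
    if displacement < MIN_DISPLACEMENT_MM:
        return 0
    if depth_change < DEPTH_CHANGE_MM:
        return 1 if rot < LARGE_ROT_DEG else 2
    if rot < SMALL_ROT_DEG:
        return 3
    if rot <= LARGE_ROT_DEG:
        return 4
    return 5


def _look_at(position: np.ndarray, target: np.ndarray,
             roll_deg: float = 0.0) -> RigidTransform:
    """Camera pose ``^g^T_c`` with +z aimed at ``target``."""
    z = _unit(target - position)
    e1, e2 = _orthonormal_basis(z)
    R = np.column_stack([e1, e2, z])
    R = R @ Rotation.from_euler("z", roll_deg, degrees=True).as_matrix()
    return RigidTransform(R, position, from_frame="camera",
                          to_frame="generator")


def _polyp_visible(scene: Scene, pose: RigidTransform,
                   margin_px: float = 12.0) -> bool:
    try:
        uv = project(scene.camera, invert(pose), scene.border_points_3d[::6])
    except Exception:
        return False
    w, h = scene.camera.width, scene.camera.height
    return bool(np.all((uv[:, 0] >= margin_px) & (uv[:, 0] <= w - margin_px)
                       & (uv[:, 1] >= margin_px) & (uv[:, 1] <= h - margin_px)))


def _base_pose(scene: Scene, depth_mm: float,
               rng: np.random.Generator) -> RigidTransform:
    """First camera pose: roughly frontal view of the polyp at a depth."""
    tilt = Rotation.from_rotvec(rng.normal(0, 0.06, 3)).as_matrix()
    view_dir = _unit(tilt @ scene.polyp_normal)
    pos = scene.polyp_center + depth_mm * view_dir
    return _look_at(pos, scene.polyp_center, roll_deg=rng.uniform(-180, 180))


def _second_pose(scene: Scene, pose1: RigidTransform, depth_mm: float,
                 movement_type: int, rng: np.random.Generator
                 ) -> RigidTransform:
    R1, p1 = pose1.rotation, pose1.translation
    xc, yc, zc = R1[:, 0], R1[:, 1], R1[:, 2]

    def lateral(mag):
        phi = rng.uniform(0, 2 * np.pi)
        return mag * (np.cos(phi) * xc + np.sin(phi) * yc)

    if movement_type == 0:
        d = rng.uniform(0.8, 2.5) * _unit(rng.normal(size=3))
        rot = Rotation.from_rotvec(
            np.radians(rng.uniform(0, 6)) * _unit(rng.normal(size=3)))
        return RigidTransform(rot.as_matrix() @ R1, p1 + d,
                              from_frame="camera", to_frame="generator")

    # Lateral drift is about half the viewing depth (the operator keeps
    # the polyp in the wide field of view); re-aim rotation is small for
    # the "good" movement types — the affine border transfer is exact for
    # rotation-free lateral motion of a planar target, and its model
    # error grows with the rotation magnitude.
    if movement_type in (1, 2):
        L = rng.uniform(0.38, 0.60) * depth_mm
        dz = rng.uniform(-1.5, 1.5)
    elif movement_type == 3:
        L = rng.uniform(0.0, 2.0)
        dz = rng.choice([-1, 1]) * rng.uniform(4, 12)
    elif movement_type == 4:
        L = rng.uniform(0.30, 0.50) * depth_mm
        dz = rng.choice([-1, 1]) * rng.uniform(4, 10)
    elif movement_type == 5:
        L = rng.uniform(0.38, 0.60) * depth_mm
        dz = rng.choice([-1, 1]) * rng.uniform(4, 10)
    else:
        raise ValueError(f"movement type must be 0..5, got {movement_type}")

    p2 = p1 + lateral(L) + dz * zc
    if movement_type == 3:
        rot = Rotation.from_rotvec(
            np.radians(rng.uniform(0, 3)) * _unit(rng.normal(size=3)))
        return RigidTransform(rot.as_matrix() @ R1, p2,
                              from_frame="camera", to_frame="generator")

    # rotation target per type; the camera re-aims toward the polyp by
    # that amount (types 2 and 5 add extra pan past the re-aim if needed)
    if movement_type == 1:
        target = rng.uniform(0.5, 6.0)
    elif movement_type == 4:
        target = rng.uniform(6.0, 18.0)
    else:  # 2, 5
        target = rng.uniform(21.0, 28.0)
    aim = _look_at(p2, scene.polyp_center)
    rel = Rotation.from_matrix(R1.T @ aim.rotation)
    ang = np.degrees(np.linalg.norm(rel.as_rotvec()))
    if ang >= target or movement_type in (1, 4):
        f = min(1.0, target / max(ang, 1e-9))
        R2 = R1 @ Rotation.from_rotvec(rel.as_rotvec() * f).as_matrix()
    else:
        axis = _unit(np.cross(zc, _unit(scene.polyp_center - p2))
                     + rng.normal(0, 1e-3, 3))
        extra = Rotation.from_rotvec(np.radians(target - ang) * axis)
        R2 = extra.as_matrix() @ aim.rotation
    return RigidTransform(R2, p2, from_frame="camera", to_frame="generator")


def sample_pose_pair(scene: Scene, movement_type: int, depth_mm: float,
                     seed: int = 0, max_attempts: int = 400
                     ) -> tuple[RigidTransform, RigidTransform]:
    """Rejection-sample a camera pose pair of the requested movement type.

    Both poses keep the polyp fully in frame, the first at the requested
    viewing depth (within 10%); the pair classifies exactly to
    ``movement_type``.  Deterministic given the seed.
    """
    if movement_type not in range(6):
        raise ValueError("movement type must be in 0..5")
    if depth_mm <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        d1 = depth_mm * rng.uniform(0.97, 1.03)
        pose1 = _base_pose(scene, d1, rng)
        if not _polyp_visible(scene, pose1):
            continue
        pose2 = _second_pose(scene, pose1, d1, movement_type, rng)
        if not _polyp_visible(scene, pose2):
            continue
        if classify_movement(pose1, pose2) != movement_type:
            continue
        return pose1, pose2
    raise RuntimeError(
        f"could not sample a valid type-{movement_type} pair at depth "
        f"{depth_mm} mm after {max_attempts} attempts")


def sample_pose_set(scene: Scene, n: int, depth_mm: float,
                    seed: int = 0) -> list[RigidTransform]:
    """Sample ``n`` poses viewing the polyp from different angles, such
    that consecutive poses are lateral (type 1/2-style) moves — the
    four-image capture protocol behind approach B."""
    rng = np.random.default_rng(seed)
    poses = []
    for _ in range(400):
        d1 = depth_mm * rng.uniform(0.97, 1.03)
        pose = _base_pose(scene, d1, rng)
        if _polyp_visible(scene, pose):
            poses = [pose]
            break
    while len(poses) < n:
        mtype = int(rng.choice([1, 1, 1, 4]))  # mostly depth-preserving
        for _ in range(400):
            cand = _second_pose(scene, poses[-1], depth_mm, mtype, rng)
            if _polyp_visible(scene, cand):
                poses.append(cand)
                break
        else:
            raise RuntimeError("pose-set sampling failed")
    return poses


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

def _texture(shape: tuple[int, int], seed: int) -> np.ndarray:
    """Band-limited procedural texture tile in [-1, 1]."""
    rng = np.random.default_rng(seed)
    fine = ndimage.gaussian_filter(rng.standard_normal(shape), 1.2)
    coarse = ndimage.gaussian_filter(rng.standard_normal(shape), 5.0)
    t = fine / fine.std() + 0.8 * coarse / coarse.std()
    return t / np.abs(t).max()


def _render_image(scene: Scene, pose: RigidTransform) -> np.ndarray:
    cam = scene.camera
    h, w = cam.height, cam.width
    uu, vv = np.meshgrid(np.arange(w, dtype=float),
                         np.arange(h, dtype=float))
    uv = np.column_stack([uu.ravel(), vv.ravel()])
    xy = cam.undistort_normalized(cam.pixel_to_normalized(uv))
    dirs_cam = np.column_stack([xy, np.ones(len(xy))])
    dirs = dirs_cam @ pose.rotation.T
    origin = pose.translation

    n = scene.polyp_normal
    denom = dirs @ n
    tnum = np.dot(scene.polyp_center - origin, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = tnum / denom
    hit = np.isfinite(tt) & (tt > 0)
    pts = origin + dirs * tt[:, None]
    rel = pts - scene.polyp_center
    s1 = rel @ scene.plane_e1
    s2 = rel @ scene.plane_e2
    rho = np.hypot(s1, s2)

    tex = _texture((256, 256), scene.texture_seed)
    texp = _texture((256, 256), scene.texture_seed + 1)
    scale = 4.0  # texture px per mm
    coords = np.array([np.mod(s2 * scale, 256), np.mod(s1 * scale, 256)])
    bg_t = ndimage.map_coordinates(tex, coords, order=1, mode="wrap")
    fg_t = ndimage.map_coordinates(texp, coords * 2.7 % 256, order=1,
                                   mode="wrap")

    r = scene.polyp_radius_mm
    inside = hit & (rho <= r)
    intensity = np.where(hit, 122.0 + 42.0 * bg_t, 25.0)
    with np.errstate(invalid="ignore"):
        dome = np.sqrt(np.clip(1.0 - (rho / r) ** 2, 0.0, 1.0))
    ip = 48.0 + 22.0 * dome + 8.0 * fg_t
    intensity = np.where(inside, ip, intensity)

    # mild vignetting of the wide-angle optics
    rpx = np.hypot(uv[:, 0] - cam.cx, uv[:, 1] - cam.cy)
    vig = 1.0 - 0.22 * (rpx / rpx.max()) ** 2
    intensity *= vig

    rgb_scale = np.where(inside[:, None],
                         np.array([[1.0, 0.45, 0.40]]),
                         np.array([[0.95, 0.62, 0.52]]))
    img = np.clip(intensity[:, None] * rgb_scale, 0, 255).astype(np.uint8)
    return img.reshape(h, w, 3)


def _ground_truth_mask(scene: Scene, pose: RigidTransform) -> np.ndarray:
    from skimage.draw import polygon

    cam = scene.camera
    uv = project(cam, invert(pose), scene.border_points_3d)
    mask = np.zeros((cam.height, cam.width), bool)
    rr, cc = polygon(uv[:, 1], uv[:, 0], shape=mask.shape)
    mask[rr, cc] = True
    return mask


def render_observation(scene: Scene, pose: RigidTransform,
                       mode: str = "correspondence",
                       frame_id: int = 0) -> Observation:
    """Render one noise-free observation of the scene from a camera pose."""
    if not _polyp_visible(scene, pose, margin_px=0.0):
        raise RuntimeError("polyp out of frame; cannot render")
    cam = scene.camera
    border = project(cam, invert(pose), scene.border_points_3d)
    feats = project(cam, invert(pose), scene.feature_points_3d)
    in_frame = ((feats[:, 0] >= 0) & (feats[:, 0] <= cam.width - 1)
                & (feats[:, 1] >= 0) & (feats[:, 1] <= cam.height - 1))
    gTs = compose(pose.relabel("camera", "generator"), scene.hand_eye)
    reading = transform_to_sensor(gTs, frame_id=frame_id)
    obs = Observation(sensor=reading, border_px=border,
                      feature_px=np.where(in_frame[:, None], feats, np.nan),
                      true_pose=pose, true_sensor=reading, frame_id=frame_id)
    if mode == "image":
        obs.image = _render_image(scene, pose)
        obs.mask = _ground_truth_mask(scene, pose)
    elif mode != "correspondence":
        raise ValueError(f"unknown observation mode {mode!r}")
    return obs


def add_sensor_noise(r: SensorReading, spec: NoiseSpec,
                     rng: np.random.Generator | None = None) -> SensorReading:
    """Perturb a reading with tracker noise.

    Position noise is isotropic with per-axis sigma ``sigma_t/sqrt(3)`` so
    the 3D position RMSE equals ``sigma_t``; orientation is rotated about
    a uniformly random axis by ``|N(0, sigma_r)]`` degrees.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.sigma_t == 0 and spec.sigma_r == 0:
        return r
    T = sensor_to_transform(r)
    pos = T.translation + rng.normal(0, spec.sigma_t / np.sqrt(3), 3)
    angle = abs(rng.normal(0.0, np.radians(spec.sigma_r)))
    axis = _unit(rng.normal(size=3))
    R = Rotation.from_rotvec(angle * axis).as_matrix() @ T.rotation
    return transform_to_sensor(
        RigidTransform(R, pos, from_frame="sensor", to_frame="generator"),
        frame_id=r.frame_id)


def make_observation_pair(scene: Scene, pose1: RigidTransform,
                          pose2: RigidTransform,
                          noise: NoiseSpec | None = None,
                          mode: str = "correspondence",
                          seed: int = 0) -> tuple[Observation, Observation]:
    """Render a pair and apply sensor + correspondence noise to it."""
    obs1 = render_observation(scene, pose1, mode=mode, frame_id=0)
    obs2 = render_observation(scene, pose2, mode=mode, frame_id=1)
    if noise is None:
        return obs1, obs2
    rng = np.random.default_rng(seed)
    for obs in (obs1, obs2):
        obs.sensor = add_sensor_noise(obs.true_sensor, noise, rng)
        if noise.sigma_px > 0 and obs.feature_px is not None:
            obs.feature_px = obs.feature_px + rng.normal(
                0, noise.sigma_px, obs.feature_px.shape)
    return obs1, obs2
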