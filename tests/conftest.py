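import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from endosize.calibration import CheckerboardSpec
from endosize.geometry import CameraModel, RigidTransform, compose, invert
from endosize.simulator import make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def camera():
    return CameraModel(fx=310.0, fy=305.0, cx=240.3, cy=238.2,
                       width=480, height=480, k1=-0.15, k2=0.02)


@pytest.fixture
def pinhole():
    return CameraModel(fx=500.0, fy=500.0, cx=320.0, cy=240.0,
                       width=640, height=480)


@pytest.fixture
def scene():
    return make_scene(seed=1)


def random_transform(rng, scale_mm=50.0, from_frame="scene",
                     to_frame="scene"):
    return RigidTransform(Rotation.random(rng=rng).as_matrix(),
                          rng.uniform(-scale_mm, scale_mm, 3),
                          from_frame=from_frame, to_frame=to_frame)


def checkerboard_views(camera, spec, n_views, rng, distance_mm=55.0):
    """Synthetic checkerboard corner observations with known extrinsics."""
    obj = spec.object_points()
    views, poses = [], []
    while len(views) < n_views:
        R = Rotation.from_rotvec(rng.normal(0, 0.25, 3)).as_matrix()
        t = np.array([0.0, 0.0, distance_mm]) + rng.uniform(-8, 8, 3)
        T = RigidTransform(R, t, from_frame="pattern", to_frame="camera")
        Xc = T.apply(obj)
        if not (Xc[:, 2] > 10).all():
            continue
        xy = Xc[:, :2] / Xc[:, 2:3]
        uv = camera.normalized_to_pixel(camera.distort_normalized(xy))
        if ((uv[:, 0] > 5).all() and (uv[:, 0] < camera.width - 5).all()
                and (uv[:, 1] > 5).all()
                and (uv[:, 1] < camera.height - 5).all()):
            views.append(uv)
            poses.append(T)
    return views, poses


def handeye_dataset(rng, n_poses=12, camera=None, spec=None):
    """Camera extrinsics + sensor poses generated from a known hand-eye
    transform X (sensor frame -> camera frame)."""
    if camera is None:
        camera = CameraModel(fx=310.0, fy=305.0, cx=240.3, cy=238.2,
                             width=480, height=480)
    if spec is None:
        spec = CheckerboardSpec(8, 9, 3.0)
    _, extrinsics = checkerboard_views(camera, spec, n_poses, rng)
    X = random_transform(rng, scale_mm=20.0, from_frame="sensor",
                         to_frame="camera")
    gTp = random_transform(rng, scale_mm=60.0, from_frame="pattern",
                           to_frame="generator")
    sensor_poses = [compose(compose(gTp, invert(T)), X) for T in extrinsics]
    return extrinsics, sensor_poses, X
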