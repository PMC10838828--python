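"""Two-view metric reconstruction of the polyp border.

The relative camera pose between the two captures is obtained from the
tracker readings and the hand-eye transform; border correspondences are
triangulated by the linear (DLT) method; a planar ellipse is fitted to the
3D border points.  The fitted major-axis length is the polyp size and the
ellipse-centre z coordinate in the first camera's frame is the depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    CameraModel,
    RigidTransform,
    SensorReading,
    compose,
    invert,
    sensor_to_transform,
)

__all__ = [
    "Ellipse3D",
    "PolypMeasurement",
    "InsufficientBaselineError",
    "relative_camera_pose",
    "triangulate",
    "fit_ellipse_3d",
    "polyp_location",
    "distance_to_landmark",
]


class InsufficientBaselineError(RuntimeError):
    """Camera centres are (nearly) coincident: triangulation rays are
    near-parallel and the intersection point is ill-determined."""


@dataclass
class Ellipse3D:
    """Planar ellipse in 3D (camera-1 frame, mm); axis lengths are full
    lengths (diameters)."""

    center: np.ndarray
    normal: np.ndarray
    major_axis_length: float
    minor_axis_length: float
    major_axis_direction: np.ndarray
    rms_residual_mm: float = 0.0
    fallback_enclosing: bool = False

    def __post_init__(self):
        self.center = np.asarray(self.center, float).reshape(3)
        self.normal = np.asarray(self.normal, float).reshape(3)
        self.major_axis_direction = np.asarray(
            self.major_axis_direction, float).reshape(3)
        if not self.major_axis_length >= self.minor_axis_length > 0:
            raise ValueError("require major >= minor > 0")


@dataclass
class PolypMeasurement:
    """One size/depth/location estimate from a single image pair (or an
    aggregate over several pairs)."""

    size_mm: float
    depth_mm: float
    center_camera1_mm: np.ndarray
    center_generator_mm: np.ndarray | None = None
    distance_to_landmark_mm: float | None = None
    n_points: int = 0
    rms_residual_mm: float = 0.0
    flags: list[str] = field(default_factory=list)
    ellipse: Ellipse3D | None = None


def relative_camera_pose(s1: SensorReading | RigidTransform,
                         s2: SensorReading | RigidTransform,
                         handeye: RigidTransform) -> RigidTransform:
    """Relative camera pose ``^c1^T_c2`` from two tracker readings.

    ``handeye`` is the hand-eye calibration result: it maps sensor-frame
    coordinates into the camera frame.  The chain is
    ``X · inv(gTs1) · gTs2 · inv(X)`` with ``X`` the hand-eye transform.
    """
    g1 = sensor_to_transform(s1) if isinstance(s1, SensorReading) else s1
    g2 = sensor_to_transform(s2) if isinstance(s2, SensorReading) else s2
    X = handeye.relabel("sensor", "camera")
    g1 = g1.relabel("sensor", "generator")
    g2 = g2.relabel("sensor", "generator")
    rel = compose(compose(compose(X, invert(g1)), g2), invert(X))
    return rel.relabel("camera", "camera")


def triangulate(cam: CameraModel, relpose: RigidTransform,
                pts1: np.ndarray, pts2: np.ndarray,
                baseline_min: float = 0.5,
                method: str = "dlt") -> tuple[np.ndarray, np.ndarray]:
    """Two-view triangulation of undistorted pixel correspondences.

    ``relpose`` is ``^c1^T_c2``.  Returns ``(points (N, 3) in the camera-1
    frame, valid (N,) bool)``; points reconstructed behind either camera
    are flagged invalid (cheirality) and returned as NaN.

    A midpoint-method alternative (``method='midpoint'``) is kept for
    cross-checking the linear solution.
    """
    pts1 = np.atleast_2d(np.asarray(pts1, float))
    pts2 = np.atleast_2d(np.asarray(pts2, float))
    if pts1.shape != pts2.shape:
        raise ValueError("point lists differ in shape")
    b = float(np.linalg.norm(relpose.translation))
    if b < baseline_min:
        raise InsufficientBaselineError(
            f"insufficient baseline: |t| = {b:.3g} mm < {baseline_min} mm")

    # rays in normalized camera coordinates
    x1 = cam.pixel_to_normalized(pts1)
    x2 = cam.pixel_to_normalized(pts2)
    # camera-2 projection of camera-1-frame points: X_c2 = R' X + t'
    R2 = relpose.rotation.T
    t2 = -relpose.rotation.T @ relpose.translation
    P1 = np.hstack([np.eye(3), np.zeros((3, 1))])
    P2 = np.hstack([R2, t2.reshape(3, 1)])

    n = len(x1)
    if method == "midpoint":
        X = _triangulate_midpoint(x1, x2, relpose)
    else:
        A = np.empty((n, 4, 4))
        A[:, 0] = x1[:, 0:1] * P1[2] - P1[0]
        A[:, 1] = x1[:, 1:2] * P1[2] - P1[1]
        A[:, 2] = x2[:, 0:1] * P2[2] - P2[0]
        A[:, 3] = x2[:, 1:2] * P2[2] - P2[1]
        _, _, Vt = np.linalg.svd(A)
        Xh = Vt[:, -1, :]
        X = Xh[:, :3] / Xh[:, 3:4]

    z1 = X[:, 2]
    z2 = X @ R2.T[:, 2] + t2[2]
    valid = (z1 > 0) & (z2 > 0) & np.isfinite(X).all(axis=1)
    X = X.copy()
    X[~valid] = np.nan
    return X, valid


def _triangulate_midpoint(x1, x2, relpose: RigidTransform) -> np.ndarray:
    """Closest point between the two viewing rays, in the camera-1 frame."""
    d1 = np.column_stack([x1, np.ones(len(x1))])
    d2 = (np.column_stack([x2, np.ones(len(x2))]) @ relpose.rotation.T)
    c2 = relpose.translation
    out = np.empty((len(d1), 3))
    for i, (a, b2) in enumerate(zip(d1, d2)):
        # solve [a -b2][s; t] = c2 in least squares
        M = np.column_stack([a, -b2])
        st, *_ = np.linalg.lstsq(M, c2, rcond=None)
        out[i] = 0.5 * (st[0] * a + (c2 + st[1] * b2))
    return out


def fit_ellipse_3d(points: np.ndarray, min_points: int = 6) -> Ellipse3D:
    """Fit a planar ellipse to 3D points.

    The best-fit plane comes from the principal axes of the centred
    points; the in-plane conic is fitted by the direct least-squares
    ellipse method.  If that degenerates (hyperbolic/parabolic conic), the
    minimum-area enclosing ellipse of the projected points is used and the
    result flagged.
    """
    from skimage.measure import EllipseModel

    P = np.asarray(points, float)
    P = P[np.isfinite(P).all(axis=1)]
    if len(P) < min_points:
        raise ValueError(f"need >= {min_points} non-degenerate points")
    centroid = P.mean(axis=0)
    Q = P - centroid
    _, s, Vt = np.linalg.svd(Q, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; no unique plane")
    e1, e2, normal = Vt[0], Vt[1], Vt[2]
    uv = np.column_stack([Q @ e1, Q @ e2])

    fallback = False
    model = EllipseModel.from_estimate(uv)
    params = None
    if model:
        xc, yc = model.center
        a, b = model.axis_lengths
        theta = float(model.theta)
        if np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0:
            params = (xc, yc, a, b, theta)
    if params is None:
        (xc, yc), (a, b), theta = _min_enclosing_ellipse(uv)
        params = (xc, yc, a, b, theta)
        fallback = True
    xc, yc, a, b, theta = params
    if a < b:
        a, b, theta = b, a, theta + np.pi / 2

    center3d = centroid + xc * e1 + yc * e2
    major_dir = np.cos(theta) * e1 + np.sin(theta) * e2
    major_dir = major_dir / np.linalg.norm(major_dir)
    rms = _ellipse_rms(uv, xc, yc, a, b, theta)
    return Ellipse3D(
        center=center3d, normal=normal,
        major_axis_length=2.0 * a, minor_axis_length=2.0 * b,
        major_axis_direction=major_dir, rms_residual_mm=rms,
        fallback_enclosing=fallback,
    )


def _ellipse_rms(uv, xc, yc, a, b, theta) -> float:
    """Approximate RMS point-to-ellipse distance (radial approximation)."""
    c, s = np.cos(theta), np.sin(theta)
    d = uv - [xc, yc]
    x = d[:, 0] * c + d[:, 1] * s
    y = -d[:, 0] * s + d[:, 1] * c
    phi = np.arctan2(y * a, x * b)
    ex = a * np.cos(phi) - x
    ey = b * np.sin(phi) - y
    return float(np.sqrt(np.mean(ex ** 2 + ey ** 2)))


def _min_enclosing_ellipse(pts: np.ndarray, tol: float = 1e-4):
    """Minimum-area enclosing ellipse (Khachiyan's algorithm)."""
    n, d = pts.shape
    Q = np.column_stack([pts, np.ones(n)]).T
    u = np.full(n, 1.0 / n)
    for _ in range(1000):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T @ np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1.0) * (M[j] - 1.0))
        new_u = (1 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    c = pts.T @ u
    S = (pts.T @ np.diag(u) @ pts - np.outer(c, c)) / d
    # ellipse: (x-c)' inv(S)/? (x-c) <= d ... axes from eigen-decomposition
    w, V = np.linalg.eigh(S * d)
    w = np.maximum(w, 1e-12)
    axes = np.sqrt(w)
    order = np.argsort(axes)[::-1]
    a, b = axes[order[0]], axes[order[1]]
    theta = float(np.arctan2(V[1, order[0]], V[0, order[0]]))
    return (float(c[0]), float(c[1])), (float(a), float(b)), theta


def polyp_location(e: Ellipse3D, s_at_capture: SensorReading | RigidTransform,
                   handeye: RigidTransform) -> np.ndarray:
    """Ellipse centre mapped into the generator frame (mm).

    ``handeye`` maps sensor coordinates into the camera frame, so the
    camera-to-generator chain is ``gTs · inv(handeye)``.
    """
    gTs = (sensor_to_transform(s_at_capture)
           if isinstance(s_at_capture, SensorReading) else s_at_capture)
    cam_to_gen = compose(gTs, invert(handeye.relabel("sensor", "camera")))
    return cam_to_gen.apply(e.center)


def distance_to_landmark(p_generator: np.ndarray,
                         landmark: SensorReading | np.ndarray) -> float:
    """Euclidean distance (mm) between a generator-frame point and the
    landmark position recorded when passing the Z line."""
    pos = (landmark.position if isinstance(landmark, SensorReading)
           else np.asarray(landmark, float))
    return float(np.linalg.norm(np.asarray(p_generator, float) - pos))
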