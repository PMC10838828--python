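"""Frame-aware rigid transforms and the camera projection model.

Every quantity in the package lives in one of five named frames:

``generator``
    The electromagnetic field generator (the tracker's world frame).
``sensor``
    The 6DoF electromagnetic sensor clipped to the endoscope shaft.
``camera``
    The endoscope camera: +z along the optical axis, +x right, +y down.
``pattern``
    The checkerboard calibration target.
``scene``
    A generic world frame used by the simulator.

All lengths are millimetres; pixels are 0-based with the origin at the
top-left corner of the image.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "FrameError",
    "RigidTransform",
    "CameraModel",
    "SensorReading",
    "compose",
    "invert",
    "rotation_angle",
    "rotation_axis",
    "sensor_to_transform",
    "transform_to_sensor",
    "random_rotation",
    "project",
    "undistort_points",
]


class FrameError(ValueError):
    """Raised when two transforms with incompatible frame labels are chained."""


def _project_to_rotation(M: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix in the Frobenius sense, det +1 enforced."""
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``p_to = rotation @ p_from + translation`` between two frames.

    In the superscript/subscript notation used for tracked endoscopy
    (e.g. ``^g^T_s``), ``to_frame`` is the superscript and ``from_frame``
    the subscript.
    """

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: str = "scene"
    to_frame: str = "scene"

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.isfinite(R).all() and np.isfinite(t).all()):
            raise ValueError("non-finite transform entries")
        err = np.linalg.norm(R.T @ R - np.eye(3))
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (|R'R - I| = {err:.3g})")
        if err > 1e-12:  # re-orthonormalize values read from files
            R = _project_to_rotation(R)
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, frame: str = "scene") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), from_frame=frame, to_frame=frame)

    @classmethod
    def from_matrix(cls, M: np.ndarray, from_frame: str = "scene",
                    to_frame: str = "scene") -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        return cls(M[:3, :3], M[:3, 3], from_frame=from_frame, to_frame=to_frame)

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point (3,) or many points (N, 3) into ``to_frame``."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def relabel(self, from_frame: str, to_frame: str) -> "RigidTransform":
        return dataclasses.replace(self, from_frame=from_frame, to_frame=to_frame)


def compose(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """``T1 ∘ T2``: apply ``T2`` first, then ``T1``.

    Requires ``T1.from_frame == T2.to_frame``; the result maps
    ``T2.from_frame`` to ``T1.to_frame``.
    """
    if T1.from_frame != T2.to_frame:
        raise FrameError(
            f"cannot compose: left transform expects points in "
            f"'{T1.from_frame}' but right transform produces '{T2.to_frame}'"
        )
    return RigidTransform(
        T1.rotation @ T2.rotation,
        T1.rotation @ T2.translation + T1.translation,
        from_frame=T2.from_frame,
        to_frame=T1.to_frame,
    )


def invert(T: RigidTransform) -> RigidTransform:
    return RigidTransform(
        T.rotation.T,
        -T.rotation.T @ T.translation,
        from_frame=T.to_frame,
        to_frame=T.from_frame,
    )


def rotation_angle(T: RigidTransform | np.ndarray) -> float:
    """Rotation magnitude in degrees, ``arccos((trace(R) - 1)/2)`` in [0, 180]."""
    R = T.rotation if isinstance(T, RigidTransform) else np.asarray(T)
    c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def rotation_axis(T: RigidTransform | np.ndarray) -> np.ndarray:
    """Unit rotation axis; arbitrary (x̂) for the identity rotation."""
    R = T.rotation if isinstance(T, RigidTransform) else np.asarray(T)
    rv = Rotation.from_matrix(R).as_rotvec()
    n = np.linalg.norm(rv)
    if n < 1e-12:
        return np.array([1.0, 0.0, 0.0])
    return rv / n


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure)."""
    return Rotation.random(rng=rng).as_matrix()


@dataclass(frozen=True)
class SensorReading:
    """One 6DoF electromagnetic tracker sample, in the generator frame.

    Orientation follows the tracker's native intrinsic Z-Y-X Euler
    convention: azimuth about z, then elevation about the rotated y,
    then roll about the rotated x (all degrees).
    """

    position: np.ndarray
    azimuth: float
    elevation: float
    roll: float
    frame_id: int = 0

    def __post_init__(self):
        p = np.asarray(self.position, dtype=float).reshape(3)
        ang = np.array([self.azimuth, self.elevation, self.roll], dtype=float)
        if not (np.isfinite(p).all() and np.isfinite(ang).all()):
            raise ValueError("non-finite sensor reading")
        object.__setattr__(self, "position", p)


def _wrap180(a: float) -> float:
    return float((a + 180.0) % 360.0 - 180.0)


def sensor_to_transform(r: SensorReading) -> RigidTransform:
    """Sensor pose ``^g^T_s`` from a 6DoF reading (intrinsic Z-Y-X Euler)."""
    R = Rotation.from_euler("ZYX", [r.azimuth, r.elevation, r.roll],
                            degrees=True).as_matrix()
    return RigidTransform(R, r.position, from_frame="sensor", to_frame="generator")


def transform_to_sensor(T: RigidTransform, frame_id: int = 0) -> SensorReading:
    """Inverse of :func:`sensor_to_transform` (angles normalized)."""
    az, el, roll = Rotation.from_matrix(T.rotation).as_euler("ZYX", degrees=True)
    return SensorReading(
        position=T.translation.copy(),
        azimuth=_wrap180(az),
        elevation=float(el),
        roll=_wrap180(roll),
        frame_id=frame_id,
    )


class CheiralityError(ValueError):
    """A point to be projected lies at or behind the camera (z <= 0)."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with Brown radial/tangential lens distortion.

    Projection of a camera-frame point (X, Y, Z):
    normalize ``x = X/Z, y = Y/Z``; distort with radial ``k1, k2, k3``
    and tangential ``p1, p2``; then apply the intrinsics
    ``u = fx·xd + skew·yd + cx``, ``v = fy·yd + cy``.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    skew: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point outside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array([
            [self.fx, self.skew, self.cx],
            [0.0, self.fy, self.cy],
            [0.0, 0.0, 1.0],
        ])

    @property
    def dist_coeffs(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.p1, self.p2])

    # -- normalized-coordinate distortion ---------------------------------
    def distort_normalized(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x, y = xy[:, 0], xy[:, 1]
        r2 = x * x + y * y
        radial = 1.0 + r2 * (self.k1 + r2 * (self.k2 + r2 * self.k3))
        xd = x * radial + 2 * self.p1 * x * y + self.p2 * (r2 + 2 * x * x)
        yd = y * radial + self.p1 * (r2 + 2 * y * y) + 2 * self.p2 * x * y
        return np.column_stack([xd, yd])

    def undistort_normalized(self, xy: np.ndarray, max_iter: int = 20,
                             tol: float = 1e-8) -> np.ndarray:
        """Fixed-point inversion of the distortion model."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        guess = xy.copy()
        for _ in range(max_iter):
            d = self.distort_normalized(guess)
            step = xy - d
            guess = guess + step
            if np.max(np.abs(step)) < tol:
                break
        return guess

    def normalized_to_pixel(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        u = self.fx * xy[:, 0] + self.skew * xy[:, 1] + self.cx
        v = self.fy * xy[:, 1] + self.cy
        return np.column_stack([u, v])

    def pixel_to_normalized(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        y = (uv[:, 1] - self.cy) / self.fy
        x = (uv[:, 0] - self.cx - self.skew * y) / self.fx
        return np.column_stack([x, y])


def project(cam: CameraModel, T_cam_from_scene: RigidTransform,
            X: np.ndarray) -> np.ndarray:
    """Project scene point(s) (mm) to distorted pixel coordinates.

    Raises :class:`CheiralityError` if any point maps to z <= 0 in the
    camera frame.
    """
    Xc = np.atleast_2d(T_cam_from_scene.apply(np.asarray(X, dtype=float)))
    if np.any(Xc[:, 2] <= 0):
        raise CheiralityError("point at or behind the camera (z <= 0)")
    xy = Xc[:, :2] / Xc[:, 2:3]
    uv = cam.normalized_to_pixel(cam.distort_normalized(xy))
    return uv[0] if np.asarray(X).ndim == 1 else uv


def undistort_points(cam: CameraModel, pts: np.ndarray) -> np.ndarray:
    """Map distorted pixel coordinates to ideal-pinhole pixel coordinates."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    xy = cam.undistort_normalized(cam.pixel_to_normalized(pts))
    return cam.normalized_to_pixel(xy)
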