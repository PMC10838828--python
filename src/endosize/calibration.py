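"""Camera intrinsic calibration and sensor-to-camera (hand-eye) calibration.

Intrinsics are estimated from checkerboard views by planar-target
calibration: a per-view homography, Zhang's closed-form intrinsics from the
stacked homography constraints, and a full non-linear reprojection
refinement including lens distortion.

The hand-eye calibration solves the AX = XB problem built from paired
camera/sensor motions.  Writing the rotation equation
``R_a R_t = R_t R_b`` as ``R_a R_t R_b' = R_t`` and stacking the rotation
row-major, each motion contributes the 12x12 block

    [ I9 - R_a ⊗ R_b      0    ] [vec(R_t)]   [ 0  ]
    [ I3 ⊗ t_b'        I3 - R_a] [  t_t   ] = [ t_a]

and the stacked system is solved by linear least squares, after which the
3x3 block is projected onto SO(3) and the translation re-estimated with
the rotation held fixed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import (
    CameraModel,
    RigidTransform,
    SensorReading,
    _project_to_rotation,
    compose,
    invert,
    rotation_angle,
    rotation_axis,
    sensor_to_transform,
)

__all__ = [
    "CheckerboardSpec",
    "MotionPair",
    "HandEyeResult",
    "IntrinsicsResult",
    "DegenerateMotionsError",
    "CalibrationError",
    "detect_checkerboard",
    "estimate_intrinsics",
    "build_motions",
    "select_motions",
    "handeye_solve",
]


class CalibrationError(RuntimeError):
    pass


class DegenerateMotionsError(CalibrationError):
    """Hand-eye motions whose rotation axes are (nearly) all parallel."""


@dataclass(frozen=True)
class CheckerboardSpec:
    """Planar checkerboard described by its inner-corner grid.

    The counts refer to inner corners (an "8 x 9" board has 8 x 9
    detectable saddle points), with squares of ``square_size`` mm.
    """

    inner_cols: int = 8
    inner_rows: int = 9
    square_size: float = 3.0

    def __post_init__(self):
        if self.inner_cols < 3 or self.inner_rows < 3:
            raise ValueError("need at least a 3x3 inner-corner grid")
        if self.square_size <= 0:
            raise ValueError("square_size must be positive")

    @property
    def n_corners(self) -> int:
        return self.inner_cols * self.inner_rows

    def object_points(self) -> np.ndarray:
        """Inner corners in the pattern frame (mm, z = 0), row-major."""
        jj, ii = np.meshgrid(np.arange(self.inner_cols),
                             np.arange(self.inner_rows))
        pts = np.column_stack([
            jj.ravel() * self.square_size,
            ii.ravel() * self.square_size,
            np.zeros(self.n_corners),
        ])
        return pts


# ---------------------------------------------------------------------------
# homographies
# ---------------------------------------------------------------------------

def _normalize_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = pts.mean(axis=0)
    d = np.sqrt(((pts - c) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
    return (pts - c) * s, T


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized DLT homography mapping ``src`` (N,2) onto ``dst`` (N,2)."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if len(src) < 4:
        raise ValueError("homography needs at least 4 correspondences")
    sn, Ts = _normalize_2d(src)
    dn, Td = _normalize_2d(dst)
    A = []
    for (x, y), (u, v) in zip(sn, dn):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, Vt = np.linalg.svd(np.asarray(A))
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    p = np.column_stack([pts, np.ones(len(pts))]) @ H.T
    return p[:, :2] / p[:, 2:3]


# ---------------------------------------------------------------------------
# checkerboard detection
# ---------------------------------------------------------------------------

def _grow_lattice(cand: np.ndarray) -> dict[tuple[int, int], int] | None:
    """Grow an integer lattice over corner candidates from a central seed.

    Returns a mapping (i, j) -> candidate index.  Growth proceeds by
    linear extrapolation from already-assigned neighbours, which tracks
    the perspective drift of the grid across the image.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(cand)
    seed = int(np.argmin(np.linalg.norm(cand - cand.mean(axis=0), axis=1)))
    d, idx = tree.query(cand[seed], k=min(7, len(cand)))
    vecs = cand[idx[1:]] - cand[seed]
    v1 = vecs[0]
    v2 = None
    for v in vecs[1:]:
        cosang = abs(np.dot(v, v1) / (np.linalg.norm(v) * np.linalg.norm(v1)))
        if cosang < 0.7:
            v2 = v
            break
    if v2 is None:
        return None

    grid = {(0, 0): seed}
    used = {seed}
    queue = [(0, 0)]
    while queue:
        cell = queue.pop(0)
        p = cand[grid[cell]]
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            target = (cell[0] + di, cell[1] + dj)
            if target in grid:
                continue
            opposite = (cell[0] - di, cell[1] - dj)
            if opposite in grid:
                step = p - cand[grid[opposite]]
            else:
                step = di * v2 + dj * v1
            pred = p + step
            dist, j = tree.query(pred)
            if j in used or dist > 0.3 * np.linalg.norm(step):
                continue
            grid[target] = int(j)
            used.add(int(j))
            queue.append(target)
    return grid


def detect_checkerboard(image: np.ndarray, spec: CheckerboardSpec
                        ) -> np.ndarray | None:
    """Detect and grid-order the inner corners of a checkerboard view.

    Returns the (rows*cols, 2) pixel coordinates in the same row-major
    order as :meth:`CheckerboardSpec.object_points`, or ``None`` when the
    full grid cannot be recovered.  Corner candidates come from the
    Harris response; a corner lattice is grown outward from a central
    seed, and the inner-corner window (with its orientation) is selected
    by the alternating black/white saddle contrast around each corner.
    """
    from skimage.feature import corner_harris, corner_peaks, corner_subpix

    img = np.asarray(image, float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.5:
        img = img / 255.0

    n = spec.n_corners
    resp = corner_harris(img, sigma=2.0)
    peaks = corner_peaks(resp, min_distance=4, num_peaks=int(n * 2.2),
                         threshold_rel=0.01)
    if len(peaks) < n:
        return None
    sub = corner_subpix(img, peaks, window_size=9)
    bad = ~np.isfinite(sub).all(axis=1)
    sub[bad] = peaks[bad]
    cand = sub[:, ::-1]  # (row, col) -> (u, v)

    grid = _grow_lattice(cand)
    if grid is None or len(grid) < n:
        return None
    keys = np.array(list(grid.keys()))
    imin, jmin = keys.min(axis=0)
    imax, jmax = keys.max(axis=0)
    ni, nj = imax - imin + 1, jmax - jmin + 1
    lattice = np.full((ni, nj, 2), np.nan)
    for (i, j), ci in grid.items():
        lattice[i - imin, j - jmin] = cand[ci]

    def sample(p):
        r = int(np.clip(round(p[1]), 0, img.shape[0] - 1))
        c = int(np.clip(round(p[0]), 0, img.shape[1] - 1))
        return img[r, c]

    def signed_contrast(a):
        """Mean signed saddle contrast of the four squares around every
        corner: most negative for the correctly placed and oriented grid
        (convention: dark square up-left of the first corner); weakened
        for windows that overhang the board outline; sign-flipped for a
        180-degree-rotated traversal."""
        nr, nc = a.shape[:2]
        total = 0.0
        for i in range(nr):
            for j in range(nc):
                v1 = (a[i, j + 1] - a[i, j]) if j + 1 < nc else (a[i, j] - a[i, j - 1])
                v2 = (a[i + 1, j] - a[i, j]) if i + 1 < nr else (a[i, j] - a[i - 1, j])
                p = a[i, j]
                s_mm = sample(p - 0.4 * v1 - 0.4 * v2)
                s_pp = sample(p + 0.4 * v1 + 0.4 * v2)
                s_pm = sample(p + 0.4 * v1 - 0.4 * v2)
                s_mp = sample(p - 0.4 * v1 + 0.4 * v2)
                total += ((-1) ** (i + j)) * (s_mm + s_pp - s_pm - s_mp)
        return total / (nr * nc)

    rows, cols = spec.inner_rows, spec.inner_cols
    best, best_score = None, np.inf
    for base in (lattice, np.transpose(lattice, (1, 0, 2))):
        bi, bj = base.shape[:2]
        if bi < rows or bj < cols:
            continue
        for oi in range(bi - rows + 1):
            for oj in range(bj - cols + 1):
                win = base[oi:oi + rows, oj:oj + cols]
                if not np.isfinite(win).all():
                    continue
                for a in (win, win[::-1, ::-1], win[:, ::-1], win[::-1, :]):
                    v1 = a[0, 1] - a[0, 0]
                    v2 = a[1, 0] - a[0, 0]
                    if v1[0] * v2[1] - v1[1] * v2[0] <= 0:  # mirrored
                        continue
                    score = signed_contrast(a)
                    if score < best_score:
                        best_score, best = score, a
    if best is None or best_score >= 0:
        return None
    return best.reshape(-1, 2).copy()


# ---------------------------------------------------------------------------
# intrinsic calibration (Zhang)
# ---------------------------------------------------------------------------

@dataclass
class IntrinsicsResult:
    camera: CameraModel
    extrinsics: list[RigidTransform]  # ^c^T_p per used view
    rmse_px: float
    used_views: list[int]


def _zhang_vij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array([
        H[0, i] * H[0, j],
        H[0, i] * H[1, j] + H[1, i] * H[0, j],
        H[1, i] * H[1, j],
        H[2, i] * H[0, j] + H[0, i] * H[2, j],
        H[2, i] * H[1, j] + H[1, i] * H[2, j],
        H[2, i] * H[2, j],
    ])


def _intrinsics_from_homographies(Hs: list[np.ndarray]) -> np.ndarray:
    V = []
    for H in Hs:
        V.append(_zhang_vij(H, 0, 1))
        V.append(_zhang_vij(H, 0, 0) - _zhang_vij(H, 1, 1))
    _, _, Vt = np.linalg.svd(np.asarray(V))
    b11, b12, b22, b13, b23, b33 = Vt[-1]
    v0 = (b12 * b13 - b11 * b23) / (b11 * b22 - b12 ** 2)
    lam = b33 - (b13 ** 2 + v0 * (b12 * b13 - b11 * b23)) / b11
    alpha = np.sqrt(lam / b11)
    beta = np.sqrt(lam * b11 / (b11 * b22 - b12 ** 2))
    gamma = -b12 * alpha ** 2 * beta / lam
    u0 = gamma * v0 / beta - b13 * alpha ** 2 / lam
    return np.array([[alpha, gamma, u0], [0, beta, v0], [0, 0, 1]])


def _extrinsics_from_homography(K: np.ndarray, H: np.ndarray) -> RigidTransform:
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    if (lam * (Kinv @ h3))[2] < 0:  # pattern must sit in front of the camera
        lam = -lam
    r1 = lam * Kinv @ h1
    r2 = lam * Kinv @ h2
    R = _project_to_rotation(np.column_stack([r1, r2, np.cross(r1, r2)]))
    t = lam * Kinv @ h3
    return RigidTransform(R, t, from_frame="pattern", to_frame="camera")


def estimate_intrinsics(views, spec: CheckerboardSpec,
                        image_size: tuple[int, int] | None = None,
                        refine: bool = True,
                        estimate_distortion: bool = True) -> IntrinsicsResult:
    """Planar-target calibration from checkerboard views.

    ``views`` may be images (corner detection is run on each) or
    pre-detected (n_corners, 2) pixel-coordinate arrays.  ``image_size``
    (width, height) is required when corner arrays are given.  Views where
    the full grid cannot be found are skipped with a warning; fewer than 3
    usable views is an error.
    """
    corners_per_view: list[np.ndarray] = []
    used: list[int] = []
    for i, v in enumerate(views):
        arr = np.asarray(v)
        if arr.ndim == 2 and arr.shape[1] == 2:
            corners = arr.astype(float)
        else:
            if image_size is None:
                image_size = (arr.shape[1], arr.shape[0])
            corners = detect_checkerboard(arr, spec)
        if corners is None or len(corners) != spec.n_corners:
            warnings.warn(f"checkerboard not found in view {i}; skipped")
            continue
        corners_per_view.append(corners)
        used.append(i)
    if len(corners_per_view) < 3:
        raise CalibrationError(
            f"only {len(corners_per_view)} usable views; need at least 3")
    if image_size is None:
        raise ValueError("image_size is required with pre-detected corners")

    obj2d = spec.object_points()[:, :2]
    Hs = [estimate_homography(obj2d, c) for c in corners_per_view]
    K = _intrinsics_from_homographies(Hs)
    extrinsics = [_extrinsics_from_homography(K, H) for H in Hs]

    width, height = image_size
    n_views = len(corners_per_view)
    obj3d = spec.object_points()

    def make_cam(p):
        fx, fy, cx, cy, skew = p
        return CameraModel(fx=fx, fy=fy, cx=np.clip(cx, 0, width - 1e-6),
                           cy=np.clip(cy, 0, height - 1e-6),
                           skew=skew, width=width, height=height)

    if not refine:
        cam = make_cam([K[0, 0], K[1, 1], K[0, 2], K[1, 2], K[0, 1]])
        rmse = _reprojection_rmse(cam, extrinsics, obj3d, corners_per_view)
        return IntrinsicsResult(cam, extrinsics, rmse, used)

    # joint refinement: intrinsics + distortion + per-view pose
    x0 = np.concatenate([
        [K[0, 0], K[1, 1], K[0, 2], K[1, 2], K[0, 1]],
        np.zeros(5),  # k1 k2 k3 p1 p2
        np.concatenate([
            np.concatenate([Rotation.from_matrix(T.rotation).as_rotvec(),
                            T.translation])
            for T in extrinsics
        ]),
    ])

    def unpack(x):
        fx, fy, cx, cy, skew = x[:5]
        k1, k2, k3, p1, p2 = x[5:10] if estimate_distortion else np.zeros(5)
        cam = CameraModel(fx=max(fx, 1e-3), fy=max(fy, 1e-3),
                          cx=np.clip(cx, 0, width - 1e-6),
                          cy=np.clip(cy, 0, height - 1e-6),
                          skew=skew, k1=k1, k2=k2, k3=k3, p1=p1, p2=p2,
                          width=width, height=height)
        poses = []
        for i in range(n_views):
            seg = x[10 + 6 * i:10 + 6 * i + 6]
            poses.append(RigidTransform(
                Rotation.from_rotvec(seg[:3]).as_matrix(), seg[3:],
                from_frame="pattern", to_frame="camera"))
        return cam, poses

    def residuals(x):
        cam, poses = unpack(x)
        res = []
        for T, uv in zip(poses, corners_per_view):
            Xc = T.apply(obj3d)
            xy = Xc[:, :2] / Xc[:, 2:3]
            pred = cam.normalized_to_pixel(cam.distort_normalized(xy))
            res.append((pred - uv).ravel())
        return np.concatenate(res)

    m = 2 * spec.n_corners
    sparsity = np.zeros((m * n_views, len(x0)), dtype=bool)
    sparsity[:, :10] = True
    for i in range(n_views):
        sparsity[m * i:m * (i + 1), 10 + 6 * i:10 + 6 * i + 6] = True

    sol = least_squares(residuals, x0, jac_sparsity=sparsity,
                        x_scale="jac", method="trf", max_nfev=200)
    cam, poses = unpack(sol.x)
    rmse = float(np.sqrt(np.mean(sol.fun ** 2)))
    return IntrinsicsResult(cam, poses, rmse, used)


def _reprojection_rmse(cam, extrinsics, obj3d, corners_per_view) -> float:
    errs = []
    for T, uv in zip(extrinsics, corners_per_view):
        Xc = T.apply(obj3d)
        xy = Xc[:, :2] / Xc[:, 2:3]
        pred = cam.normalized_to_pixel(cam.distort_normalized(xy))
        errs.append(((pred - uv) ** 2).sum(axis=1))
    return float(np.sqrt(np.mean(np.concatenate(errs))))


# ---------------------------------------------------------------------------
# hand-eye calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionPair:
    """Paired relative motions of the camera (A) and the sensor (B).

    ``A`` is the camera motion between two poses computed from checkerboard
    extrinsics; ``B`` is the sensor motion between the same two poses from
    tracker recordings.  For the true hand-eye transform X (sensor frame
    into camera frame), A·X = X·B.
    """

    A: RigidTransform
    B: RigidTransform
    pose_indices: tuple[int, int] = (0, 1)


@dataclass
class HandEyeResult:
    """Hand-eye solution: ``T`` maps sensor-frame points into the camera frame."""

    T: RigidTransform
    residual_rotation: float     # mean ||R_a R_t - R_t R_b||_F
    residual_translation: float  # mean ||R_a t_t + t_a - R_t t_b - t_t||, mm
    n_motions_used: int


def build_motions(camera_extrinsics: list[RigidTransform],
                  sensor_poses, pairing: str = "consecutive"
                  ) -> list[MotionPair]:
    """Pair camera and sensor relative motions between checkerboard poses.

    ``camera_extrinsics`` are the per-view ``^c^T_p``; ``sensor_poses`` are
    ``^g^T_s`` transforms or raw :class:`SensorReading` objects.  For the
    pose pair (i, j): ``A = cTp_i · inv(cTp_j)`` and
    ``B = inv(gTs_i) · gTs_j``.
    """
    sensor_T = [sensor_to_transform(s) if isinstance(s, SensorReading) else s
                for s in sensor_poses]
    if len(camera_extrinsics) != len(sensor_T):
        raise ValueError("camera extrinsics and sensor poses differ in length")
    if len(sensor_T) < 2:
        raise ValueError("need at least 2 poses")
    if pairing == "consecutive":
        pairs = [(i, i + 1) for i in range(len(sensor_T) - 1)]
    elif pairing == "all":
        pairs = list(itertools.combinations(range(len(sensor_T)), 2))
    else:
        raise ValueError(f"unknown pairing strategy {pairing!r}")
    motions = []
    for i, j in pairs:
        A = compose(camera_extrinsics[i], invert(camera_extrinsics[j]))
        B = compose(invert(sensor_T[i]), sensor_T[j])
        motions.append(MotionPair(A=A, B=B, pose_indices=(i, j)))
    return motions


def _axis_separation_deg(a1: np.ndarray, a2: np.ndarray) -> float:
    """Angle between two rotation axes, sign-invariant (degrees, 0..90)."""
    d = np.clip(abs(float(np.dot(a1, a2))), 0.0, 1.0)
    return float(np.degrees(np.arccos(d)))


def select_motions(motions: list[MotionPair], k: int,
                   min_angle_deg: float = 5.0) -> list[MotionPair]:
    """Greedy pose-selection heuristic for hand-eye inputs.

    Discards motions with rotation magnitude below ``min_angle_deg``, then
    greedily builds a subset of size ``k`` that maximizes the minimum
    pairwise angle between rotation axes (larger rotation magnitude breaks
    ties).  This implements the two selection suggestions that can be
    applied after capture: spread the rotation axes and favour large
    rotations.
    """
    if k > len(motions):
        raise ValueError("k exceeds number of motions")
    survivors = [m for m in motions if rotation_angle(m.A) >= min_angle_deg]
    if len(survivors) <= k:
        if len(survivors) < k:
            warnings.warn(
                f"only {len(survivors)} motions exceed {min_angle_deg} deg; "
                "returning all of them")
        return survivors
    axes = [rotation_axis(m.A) for m in survivors]
    angles = [rotation_angle(m.A) for m in survivors]
    selected = [int(np.argmax(angles))]
    while len(selected) < k:
        best_i, best_key = None, None
        for i in range(len(survivors)):
            if i in selected:
                continue
            min_sep = min(_axis_separation_deg(axes[i], axes[j])
                          for j in selected)
            key = (min_sep, angles[i])
            if best_key is None or key > best_key:
                best_key, best_i = key, i
        selected.append(best_i)
    return [survivors[i] for i in selected]


def handeye_solve(motions: list[MotionPair],
                  degeneracy_tol_deg: float = 1.0) -> HandEyeResult:
    """Solve AX = XB by the stacked homogeneous linear system.

    Raises :class:`DegenerateMotionsError` when all rotation axes are
    within ``degeneracy_tol_deg`` of one line (the translation component
    along the common axis is then unobservable).
    """
    if len(motions) < 2:
        raise ValueError("hand-eye calibration needs at least 2 motions")
    axes = [rotation_axis(m.A) for m in motions]
    max_sep = max(_axis_separation_deg(a1, a2)
                  for a1, a2 in itertools.combinations(axes, 2))
    if max_sep <= degeneracy_tol_deg:
        raise DegenerateMotionsError(
            "all motion rotation axes are parallel within "
            f"{degeneracy_tol_deg} deg (max pairwise separation "
            f"{max_sep:.3g} deg): hand-eye translation is unobservable")

    n = len(motions)
    M = np.zeros((12 * n, 12))
    rhs = np.zeros(12 * n)
    I9, I3 = np.eye(9), np.eye(3)
    for i, m in enumerate(motions):
        Ra, ta = m.A.rotation, m.A.translation
        Rb, tb = m.B.rotation, m.B.translation
        r = 12 * i
        M[r:r + 9, :9] = I9 - np.kron(Ra, Rb)
        M[r + 9:r + 12, :9] = np.kron(I3, tb.reshape(1, 3))
        M[r + 9:r + 12, 9:] = I3 - Ra
        rhs[r + 9:r + 12] = ta
    x, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    Rt = _project_to_rotation(x[:9].reshape(3, 3))  # row-major vec

    # re-estimate translation with the rotation fixed
    Ablocks = np.concatenate([I3 - m.A.rotation for m in motions])
    bblocks = np.concatenate([m.A.translation - Rt @ m.B.translation
                              for m in motions])
    tt, *_ = np.linalg.lstsq(Ablocks, bblocks, rcond=None)

    rres = float(np.mean([
        np.linalg.norm(m.A.rotation @ Rt - Rt @ m.B.rotation)
        for m in motions]))
    tres = float(np.mean([
        np.linalg.norm(m.A.rotation @ tt + m.A.translation
                       - Rt @ m.B.translation - tt)
        for m in motions]))
    T = RigidTransform(Rt, tt, from_frame="sensor", to_frame="camera")
    return HandEyeResult(T=T, residual_rotation=rres,
                         residual_translation=tres, n_motions_used=n)
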