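"""Feature detection, sparse tracking, epipolar outlier rejection and the
affine border transfer between the two images of a measurement pair.

Features are detected in a margin around the segmented polyp border in
image 1 and tracked into image 2 with a pyramidal Lucas-Kanade tracker
(with a forward-backward consistency check).  Matches inconsistent with
the epipolar geometry implied by the tracked relative camera pose are
flagged as outliers, a robust 2D affine map is fitted to the survivors,
and the full border polygon is transferred through that map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.measure import ransac
from skimage.transform import AffineTransform

from .geometry import CameraModel, RigidTransform

__all__ = [
    "MatchSet",
    "Affine2D",
    "detect_features",
    "track_features",
    "filter_epipolar",
    "estimate_affine",
    "transfer_border",
]


@dataclass
class MatchSet:
    """Parallel point lists in image 1 / image 2 with inlier flags."""

    pts1: np.ndarray  # (N, 2) pixel coordinates
    pts2: np.ndarray
    inliers: np.ndarray  # (N,) bool
    method: str = "SIFT"

    def __post_init__(self):
        self.pts1 = np.asarray(self.pts1, float).reshape(-1, 2)
        self.pts2 = np.asarray(self.pts2, float).reshape(-1, 2)
        self.inliers = np.asarray(self.inliers, bool).reshape(-1)
        if not (len(self.pts1) == len(self.pts2) == len(self.inliers)):
            raise ValueError("match lists differ in length")

    def __len__(self) -> int:
        return len(self.pts1)

    @property
    def n_inliers(self) -> int:
        return int(self.inliers.sum())

    def inlier_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.pts1[self.inliers], self.pts2[self.inliers]


@dataclass
class Affine2D:
    """2D affine map ``p2 = M[:, :2] @ p1 + M[:, 2]`` (pixels)."""

    matrix: np.ndarray  # (2, 3)
    inlier_count: int = 0
    mean_residual_px: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) <= 1e-6:
            raise ValueError("affine linear part is singular")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]


def detect_features(image: np.ndarray, roi: np.ndarray, margin_px: int = 30,
                    method: str = "SIFT") -> tuple[np.ndarray, np.ndarray]:
    """Detect keypoints with descriptors inside the ROI dilated by a margin.

    Returns ``(keypoints (N, 2) as (u, v), descriptors (N, D))``; both
    empty when nothing is detected (uniform images).
    """
    from skimage.feature import SIFT, ORB

    img = np.asarray(image, float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() > 1.5:
        img = img / 255.0
    roi = np.asarray(roi, bool)
    if roi.sum() == 0:
        raise ValueError("empty ROI")
    region = roi if margin_px == 0 else morphology.dilation(
        roi, morphology.disk(margin_px))

    if method.upper() == "SIFT":
        det = SIFT()
    elif method.upper() == "ORB":
        det = ORB()
    else:
        raise ValueError(f"unsupported detector {method!r}")
    try:
        det.detect_and_extract(img)
    except RuntimeError:  # no features at all
        return np.empty((0, 2)), np.empty((0, 0))
    kp = det.keypoints  # (row, col)
    rows = np.clip(kp[:, 0].round().astype(int), 0, region.shape[0] - 1)
    cols = np.clip(kp[:, 1].round().astype(int), 0, region.shape[1] - 1)
    keep = region[rows, cols]
    return kp[keep][:, ::-1].astype(float), np.asarray(det.descriptors)[keep]


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade tracking
# ---------------------------------------------------------------------------

def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [img]
    for _ in range(levels - 1):
        smoothed = ndimage.gaussian_filter(pyr[-1], 1.0)
        pyr.append(smoothed[::2, ::2])
    return pyr


def _sample(img: np.ndarray, uv: np.ndarray) -> np.ndarray:
    # map_coordinates wants (row, col)
    return ndimage.map_coordinates(img, [uv[:, 1], uv[:, 0]], order=1,
                                   mode="nearest")


def _lk_level(img1, img2, pts, guesses, win: int, n_iter: int = 15):
    """One pyramid level of LK; returns (displacements, ok flags)."""
    gy1, gx1 = np.gradient(img1)
    half = win // 2
    offs = np.stack(np.meshgrid(np.arange(-half, half + 1),
                                np.arange(-half, half + 1)), axis=-1
                    ).reshape(-1, 2).astype(float)  # (w2, 2) as (du, dv)
    d = guesses.copy()
    ok = np.ones(len(pts), bool)
    h, w = img1.shape
    for i, p in enumerate(pts):
        win1 = p + offs
        if not (0 <= p[0] < w and 0 <= p[1] < h):
            ok[i] = False
            continue
        Ix = _sample(gx1, win1)
        Iy = _sample(gy1, win1)
        I1 = _sample(img1, win1)
        G = np.array([[np.dot(Ix, Ix), np.dot(Ix, Iy)],
                      [np.dot(Ix, Iy), np.dot(Iy, Iy)]])
        if np.linalg.cond(G) > 1e8 or np.trace(G) < 1e-8:
            ok[i] = False
            continue
        Ginv = np.linalg.inv(G)
        for _ in range(n_iter):
            q = p + d[i]
            if not (-half <= q[0] < w + half and -half <= q[1] < h + half):
                ok[i] = False
                break
            diff = I1 - _sample(img2, q + offs)
            step = Ginv @ np.array([np.dot(diff, Ix), np.dot(diff, Iy)])
            d[i] += step
            if np.hypot(*step) < 0.01:
                break
    return d, ok


def _track_once(img1, img2, pts, levels: int, win: int,
                init: np.ndarray | None = None):
    pyr1 = _pyramid(img1, levels)
    pyr2 = _pyramid(img2, levels)
    d = np.zeros_like(pts) if init is None else np.tile(init, (len(pts), 1))
    ok = np.ones(len(pts), bool)
    for lvl in range(levels - 1, -1, -1):
        s = 2.0 ** lvl
        d_lvl, ok_lvl = _lk_level(pyr1[lvl], pyr2[lvl], pts / s, d / s, win)
        d = d_lvl * s
        ok &= ok_lvl
    return pts + d, ok


def track_features(img1: np.ndarray, img2: np.ndarray, keypoints: np.ndarray,
                   levels: int = 3, window: int = 21,
                   fb_tol: float = 1.0, min_ncc: float = 0.5) -> MatchSet:
    """Pyramidal Lucas-Kanade tracking of sparse points from img1 to img2.

    Tracks failing convergence, leaving the image, failing the
    forward-backward consistency check (``fb_tol`` px), or whose window
    normalized cross-correlation after convergence falls below
    ``min_ncc`` are dropped.
    """
    a = np.asarray(img1, float)
    b = np.asarray(img2, float)
    if a.shape[:2] != b.shape[:2]:
        raise ValueError("images differ in size")
    if a.ndim == 3:
        a = a.mean(axis=2)
        b = b.mean(axis=2)
    if a.max() > 1.5:
        a, b = a / 255.0, b / 255.0
    pts = np.asarray(keypoints, float).reshape(-1, 2)
    if len(pts) == 0:
        return MatchSet(np.empty((0, 2)), np.empty((0, 2)),
                        np.empty(0, bool), method="KLT")
    # seed the pyramid with the global inter-frame shift; endoscope wiggle
    # between captures routinely moves the scene by more than the pyramid's
    # native capture range
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(a, b, normalization=None)
    init = np.array([-shift[1], -shift[0]])
    fwd, ok_f = _track_once(a, b, pts, levels, window, init=init)
    back, ok_b = _track_once(b, a, fwd, levels, window, init=-init)
    fb_err = np.linalg.norm(back - pts, axis=1)
    half = window // 2
    offs = np.stack(np.meshgrid(np.arange(-half, half + 1),
                                np.arange(-half, half + 1)), axis=-1
                    ).reshape(-1, 2).astype(float)
    def ncc(p, q):
        wa = _sample(a, p + offs)
        wb = _sample(b, q + offs)
        wa = wa - wa.mean()
        wb = wb - wb.mean()
        denom = np.linalg.norm(wa) * np.linalg.norm(wb)
        return float(wa @ wb / denom) if denom > 1e-12 else 0.0

    corr = np.array([ncc(p, q) for p, q in zip(pts, fwd)])
    keep = ok_f & ok_b & (fb_err <= fb_tol) & (corr >= min_ncc)
    return MatchSet(pts[keep], fwd[keep], np.ones(keep.sum(), bool),
                    method="KLT")


# ---------------------------------------------------------------------------
# epipolar filtering and affine transfer
# ---------------------------------------------------------------------------

def _skew(t: np.ndarray) -> np.ndarray:
    return np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0.0]])


def fundamental_from_relpose(cam: CameraModel,
                             relpose: RigidTransform) -> np.ndarray:
    """F such that ``u1' F u2 = 0`` for pixel points, with ``relpose`` the
    transform ``^c1^T_c2`` mapping camera-2 coordinates into camera 1."""
    t = relpose.translation
    if np.linalg.norm(t) < 1e-9:
        raise ValueError(
            "epipolar geometry undefined for pure rotation/zero motion")
    E = _skew(t) @ relpose.rotation
    Kinv = np.linalg.inv(cam.K)
    return Kinv.T @ E @ Kinv


def sampson_distance_px(F: np.ndarray, pts1: np.ndarray,
                        pts2: np.ndarray) -> np.ndarray:
    """First-order geometric (Sampson) distance in pixels per match."""
    u1 = np.column_stack([pts1, np.ones(len(pts1))])
    u2 = np.column_stack([pts2, np.ones(len(pts2))])
    Fu2 = u2 @ F.T
    Ftu1 = u1 @ F
    num = np.einsum("ij,ij->i", u1, Fu2)
    den = Fu2[:, 0] ** 2 + Fu2[:, 1] ** 2 + Ftu1[:, 0] ** 2 + Ftu1[:, 1] ** 2
    return np.abs(num) / np.sqrt(np.maximum(den, 1e-12))


def filter_epipolar(matches: MatchSet, cam: CameraModel,
                    relpose: RigidTransform, tol_px: float = 2.0) -> MatchSet:
    """Flag matches whose Sampson distance to the epipolar geometry of the
    tracked relative pose exceeds ``tol_px`` (undistorted pixel units)."""
    F = fundamental_from_relpose(cam, relpose)
    if len(matches) == 0:
        return matches
    d = sampson_distance_px(F, matches.pts1, matches.pts2)
    return MatchSet(matches.pts1, matches.pts2,
                    matches.inliers & (d <= tol_px), method=matches.method)


def estimate_affine(matches: MatchSet, ras_tol: float = 3.0,
                    seed: int | None = 0, max_trials: int = 200) -> Affine2D:
    """Robust affine fit to the inlier matches.

    Random-sample consensus with threshold ``ras_tol`` px, followed by a
    least-squares refit on the consensus set.
    """
    p1, p2 = matches.inlier_points()
    if len(p1) < 3:
        raise ValueError(f"affine estimation needs >= 3 inliers, got {len(p1)}")
    spread = np.linalg.svd(p1 - p1.mean(axis=0), compute_uv=False)
    if spread[-1] < 1e-6:
        raise ValueError("matches are collinear; affine is ill-posed")
    if len(p1) == 3:
        model = AffineTransform.from_estimate(p1, p2)
        consensus = np.ones(3, bool)
    else:
        model, consensus = ransac(
            (p1, p2), AffineTransform, min_samples=3,
            residual_threshold=ras_tol, max_trials=max_trials,
            rng=seed)
        if model is None or consensus is None or consensus.sum() < 3:
            raise ValueError("consensus affine estimation failed")
        model = AffineTransform.from_estimate(p1[consensus], p2[consensus])
    if not model:
        raise ValueError("affine estimation failed")
    M = model.params[:2, :]
    res = np.linalg.norm(model(p1[consensus]) - p2[consensus], axis=1)
    return Affine2D(matrix=M, inlier_count=int(consensus.sum()),
                    mean_residual_px=float(res.mean()))


def transfer_border(border: np.ndarray, aff: Affine2D) -> np.ndarray:
    """Map every border point through the affine; order preserved."""
    return aff.apply(np.asarray(border, float))
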