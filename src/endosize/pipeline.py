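"""End-to-end polyp measurement and the evaluation harness.

:func:`measure_pair` chains the full algorithm on one image pair:
contrast adjustment and undistortion, polyp segmentation in image 1,
feature detection/tracking, tracker-based relative pose, epipolar outlier
rejection, affine border transfer, triangulation and 3D ellipse fitting.
:func:`aggregate_measurements` implements the two reporting protocols
(approach A: first pair only; approach B: trimmed mean of the six pairs
from four images), and :func:`run_sensitivity` drives the four synthetic
sensitivity sweeps (movement type, depth, segmentation quality, noise
scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import correspondence as corr
from . import reconstruction as rec
from . import segmentation as seg
from . import simulator as sim
from .geometry import CameraModel, RigidTransform, undistort_points
from .reconstruction import InsufficientBaselineError, PolypMeasurement
from .simulator import NoiseSpec, Observation, Scene

__all__ = [
    "Calibration",
    "PipelineConfig",
    "PipelineError",
    "EvaluationRecord",
    "measure_pair",
    "measure_observation_set",
    "aggregate_measurements",
    "relative_error",
    "summary_stats",
    "SummaryStats",
    "run_sensitivity",
    "EvalConfig",
]


@dataclass(frozen=True)
class Calibration:
    """Complete calibration: intrinsics and the hand-eye transform
    (sensor frame into camera frame)."""

    camera: CameraModel
    hand_eye: RigidTransform


class PipelineError(RuntimeError):
    """Stage failure; carries the name of the stage that failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    baseline_min_mm: float = 0.5
    epipolar_tol_px: float = 2.0
    min_epipolar_inliers: int = 8
    ras_tol_px: float = 3.0
    fb_tol_px: float = 1.0
    margin_px: int = 30
    feature_method: str = "SIFT"
    seed: int = 0
    segmentation: seg.SegmentationParams = field(
        default_factory=seg.SegmentationParams)
    # overrides (distorted image-1 pixel space), e.g. manual ROI or a
    # perturbed mask for sensitivity studies
    mask_override: np.ndarray | None = None
    border_override: np.ndarray | None = None
    landmark: np.ndarray | None = None  # generator frame, mm


def _contrast_stretch(img: np.ndarray) -> np.ndarray:
    """Linear min-max stretch per channel to the full 8-bit range."""
    img = np.asarray(img, float)
    out = np.empty_like(img)
    chans = img[..., None] if img.ndim == 2 else img
    outc = out[..., None] if img.ndim == 2 else out
    for c in range(chans.shape[-1]):
        ch = chans[..., c]
        lo, hi = ch.min(), ch.max()
        outc[..., c] = (ch - lo) / max(hi - lo, 1e-9) * 255.0
    return out.astype(np.uint8)


def _undistort_image(cam: CameraModel, img: np.ndarray) -> np.ndarray:
    """Resample an image onto the ideal (distortion-free) pinhole grid."""
    h, w = img.shape[:2]
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    uv = np.column_stack([uu.ravel(), vv.ravel()])
    src = cam.normalized_to_pixel(
        cam.distort_normalized(cam.pixel_to_normalized(uv)))
    coords = np.array([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])
    if img.ndim == 2:
        return ndimage.map_coordinates(img.astype(float), coords, order=1,
                                       mode="nearest")
    out = np.stack([
        ndimage.map_coordinates(img[..., c].astype(float), coords, order=1,
                                mode="nearest")
        for c in range(img.shape[2])], axis=-1)
    return out.astype(img.dtype)


def _image_mode_inputs(obs1: Observation, obs2: Observation,
                       calib: Calibration, config: PipelineConfig):
    """Segmentation + detection + tracking on rendered/real images.

    Returns (border1, matches), both in undistorted pixel coordinates.
    """
    cam = calib.camera
    img1 = _undistort_image(cam, _contrast_stretch(obs1.image))
    img2 = _undistort_image(cam, _contrast_stretch(obs2.image))

    if config.mask_override is not None or config.border_override is not None:
        border1 = (config.border_override if config.border_override is not None
                   else seg.mask_to_border(config.mask_override))
        border1 = undistort_points(cam, border1)
        if config.mask_override is not None:
            roi = np.asarray(config.mask_override, bool)
        else:
            roi = _border_to_mask(border1, cam.height, cam.width)
    else:
        result = seg.segment_polyp(img1, config.segmentation)
        if not result.found:
            raise PipelineError("segmentation",
                                "no polyp found; manual ROI required")
        border1, roi = result.border, result.mask

    kps, _ = corr.detect_features(img1, roi, margin_px=config.margin_px,
                                  method=config.feature_method)
    if len(kps) == 0:
        raise PipelineError("feature detection", "no keypoints detected")
    matches = corr.track_features(img1, img2, kps, fb_tol=config.fb_tol_px)
    if len(matches) == 0:
        raise PipelineError("tracking", "all tracks lost")
    return border1, matches


def _border_to_mask(border: np.ndarray, h: int, w: int) -> np.ndarray:
    from skimage.draw import polygon

    mask = np.zeros((h, w), bool)
    rr, cc = polygon(border[:, 1], border[:, 0], shape=mask.shape)
    mask[rr, cc] = True
    return mask


def _correspondence_mode_inputs(obs1: Observation, obs2: Observation,
                                calib: Calibration, config: PipelineConfig):
    cam = calib.camera
    if config.border_override is not None:
        border1 = config.border_override
    elif config.mask_override is not None:
        border1 = seg.mask_to_border(config.mask_override)
    else:
        border1 = obs1.border_px
    if border1 is None:
        raise PipelineError("segmentation", "observation carries no border")
    border1 = undistort_points(cam, border1)
    f1, f2 = obs1.feature_px, obs2.feature_px
    if f1 is None or f2 is None:
        raise PipelineError("tracking", "observations carry no correspondences")
    ok = np.isfinite(f1).all(axis=1) & np.isfinite(f2).all(axis=1)
    p1 = undistort_points(cam, f1[ok])
    p2 = undistort_points(cam, f2[ok])
    matches = corr.MatchSet(p1, p2, np.ones(len(p1), bool), method="exact")
    return border1, matches


def measure_pair(obs1: Observation, obs2: Observation, calib: Calibration,
                 config: PipelineConfig | None = None) -> PolypMeasurement:
    """Measure polyp size, depth and location from one observation pair.

    Works on image observations (full segmentation + tracking) or on
    correspondence-mode observations (exact border and matches, geometry
    only).  Stage failures raise :class:`PipelineError` with the stage
    name; a too-small camera baseline raises with stage ``triangulation``
    and the message ``insufficient baseline``.
    """
    config = config or PipelineConfig()
    flags: list[str] = []
    cam = calib.camera

    relpose = rec.relative_camera_pose(obs1.sensor, obs2.sensor,
                                       calib.hand_eye)
    baseline = float(np.linalg.norm(relpose.translation))
    if baseline < config.baseline_min_mm:
        raise PipelineError(
            "triangulation",
            f"insufficient baseline: |t| = {baseline:.3g} mm "
            f"< {config.baseline_min_mm} mm")

    if obs1.image is not None and obs2.image is not None:
        border1, matches = _image_mode_inputs(obs1, obs2, calib, config)
    else:
        border1, matches = _correspondence_mode_inputs(obs1, obs2, calib,
                                                       config)

    try:
        filtered = corr.filter_epipolar(matches, cam, relpose,
                                        tol_px=config.epipolar_tol_px)
    except ValueError as e:
        raise PipelineError("epipolar filter", str(e)) from e
    if filtered.n_inliers < max(3, config.min_epipolar_inliers,
                                len(matches) // 2):
        # tracker noise can shift the predicted epipolar geometry enough to
        # reject genuine matches wholesale; fall back to the unfiltered set
        filtered = matches
        flags.append("epipolar_fallback")

    try:
        aff = corr.estimate_affine(filtered, ras_tol=config.ras_tol_px,
                                   seed=config.seed)
    except ValueError as e:
        raise PipelineError("affine estimation", str(e)) from e
    border2 = corr.transfer_border(border1, aff)

    try:
        pts3d, valid = rec.triangulate(cam, relpose, border1, border2,
                                       baseline_min=config.baseline_min_mm)
    except InsufficientBaselineError as e:
        raise PipelineError("triangulation", str(e)) from e
    if (~valid).any():
        flags.append("cheirality_excluded")
    if valid.sum() < 6:
        raise PipelineError("triangulation",
                            f"only {int(valid.sum())} valid 3D points")

    try:
        ellipse = rec.fit_ellipse_3d(pts3d[valid])
    except ValueError as e:
        raise PipelineError("ellipse fit", str(e)) from e
    if ellipse.fallback_enclosing:
        flags.append("ellipse_fallback")

    center_g = rec.polyp_location(ellipse, obs1.sensor, calib.hand_eye)
    dist = (rec.distance_to_landmark(center_g, config.landmark)
            if config.landmark is not None else None)
    return PolypMeasurement(
        size_mm=ellipse.major_axis_length,
        depth_mm=float(ellipse.center[2]),
        center_camera1_mm=ellipse.center,
        center_generator_mm=center_g,
        distance_to_landmark_mm=dist,
        n_points=int(valid.sum()),
        rms_residual_mm=ellipse.rms_residual_mm,
        flags=flags,
        ellipse=ellipse,
    )


def measure_observation_set(observations: list[Observation],
                            calib: Calibration,
                            config: PipelineConfig | None = None
                            ) -> list[PolypMeasurement]:
    """Measure every pair (i < j) of a multi-image capture set."""
    out = []
    for i in range(len(observations)):
        for j in range(i + 1, len(observations)):
            out.append(measure_pair(observations[i], observations[j],
                                    calib, config))
    return out


# ---------------------------------------------------------------------------
# aggregation and metrics
# ---------------------------------------------------------------------------

def _trimmed_mean(values: np.ndarray) -> float:
    """Drop exactly one minimum and one maximum (stable index order) and
    average the rest."""
    values = np.asarray(values, float)
    imin = int(np.argmin(values))
    rest = np.delete(values, imin)
    imax = int(np.argmax(rest))
    rest = np.delete(rest, imax)
    return float(rest.mean())


def aggregate_measurements(estimates: list[PolypMeasurement],
                           mode: str = "A") -> PolypMeasurement:
    """Final estimate from one or several pair measurements.

    Approach ``A`` uses the first pair only.  Approach ``B`` expects the
    six pair estimates from a four-image capture, drops one minimum and
    one maximum and averages the remaining four (applied to size, depth
    and location component-wise).
    """
    if mode == "A":
        if len(estimates) < 1:
            raise ValueError("approach A needs at least one estimate")
        return estimates[0]
    if mode != "B":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if len(estimates) != 6:
        raise ValueError(
            f"approach B needs exactly 6 estimates, got {len(estimates)}")
    sizes = np.array([e.size_mm for e in estimates])
    depths = np.array([e.depth_mm for e in estimates])
    centers = np.array([e.center_generator_mm for e in estimates], float)
    dists = [e.distance_to_landmark_mm for e in estimates]
    agg_center = (np.array([_trimmed_mean(centers[:, k]) for k in range(3)])
                  if np.isfinite(centers).all() else None)
    agg_dist = (_trimmed_mean(np.array(dists, float))
                if all(d is not None for d in dists) else None)
    flags = sorted({f for e in estimates for f in e.flags})
    return PolypMeasurement(
        size_mm=_trimmed_mean(sizes),
        depth_mm=_trimmed_mean(depths),
        center_camera1_mm=np.full(3, np.nan),
        center_generator_mm=agg_center,
        distance_to_landmark_mm=agg_dist,
        n_points=int(sum(e.n_points for e in estimates)),
        rms_residual_mm=float(np.mean([e.rms_residual_mm for e in estimates])),
        flags=flags,
    )


def relative_error(est: float, actual: float) -> float:
    """Percentage error ``100 |est - actual| / actual``."""
    if actual <= 0:
        raise ValueError("actual value must be positive")
    return 100.0 * abs(est - actual) / actual


@dataclass
class SummaryStats:
    mean: float
    sd: float                 # sample SD (n-1)
    rmse: float               # vs the actual value
    cov_pct: float            # 100 * SD / mean
    mean_error_pct: float     # mean of per-value relative errors
    sd_error_pct: float
    n: int


def summary_stats(values, actual: float) -> SummaryStats:
    """Accuracy metrics of repeated measurements against a known value."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if actual <= 0:
        raise ValueError("actual value must be positive")
    errs = 100.0 * np.abs(v - actual) / actual
    sd = float(v.std(ddof=1))
    mean = float(v.mean())
    return SummaryStats(
        mean=mean, sd=sd,
        rmse=float(np.sqrt(np.mean((v - actual) ** 2))),
        cov_pct=100.0 * sd / mean,
        mean_error_pct=float(errs.mean()),
        sd_error_pct=float(errs.std(ddof=1)),
        n=len(v),
    )


# ---------------------------------------------------------------------------
# sensitivity sweeps
# ---------------------------------------------------------------------------

@dataclass
class EvaluationRecord:
    """Per-condition trial results of a sensitivity sweep."""

    condition: str
    estimates_mm: list[float]
    errors_pct: list[float]
    n_failed: int = 0

    @property
    def mean_error_pct(self) -> float:
        return float(np.mean(self.errors_pct)) if self.errors_pct else np.nan

    @property
    def sd_error_pct(self) -> float:
        return (float(np.std(self.errors_pct, ddof=1))
                if len(self.errors_pct) > 1 else np.nan)

    @property
    def median_error_pct(self) -> float:
        return float(np.median(self.errors_pct)) if self.errors_pct else np.nan


@dataclass
class EvalConfig:
    scene_config: sim.SceneConfig = field(default_factory=sim.SceneConfig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    mode: str = "correspondence"
    depth_range_mm: tuple[float, float] = (25.0, 40.0)
    depth_grid_mm: tuple[float, ...] = (7, 10, 15, 20, 25, 30, 35, 40,
                                        45, 50, 55, 58)
    dsc_grid: tuple[float, ...] = (1.0, 0.95, 0.90, 0.85, 0.80)
    dsc_depth_mm: float = 26.7
    noise_multipliers: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)
    movement_types: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    base_seed: int = 0


def measure_synthetic_pair(scene: Scene, movement_type: int, depth_mm: float,
                           noise: NoiseSpec | None, seed: int,
                           mode: str = "correspondence",
                           config: PipelineConfig | None = None
                           ) -> PolypMeasurement:
    """Sample a pose pair, render it, and run the measurement pipeline."""
    pose1, pose2 = sim.sample_pose_pair(scene, movement_type, depth_mm,
                                        seed=seed)
    obs1, obs2 = sim.make_observation_pair(scene, pose1, pose2, noise=noise,
                                           mode=mode, seed=seed + 1)
    calib = Calibration(scene.camera, scene.hand_eye)
    return measure_pair(obs1, obs2, calib, config)


def _sweep_trial(scene, mtype, depth, noise, seed, mode, errors, estimates,
                 failures):
    try:
        m = measure_synthetic_pair(scene, mtype, depth, noise, seed,
                                   mode=mode)
        estimates.append(m.size_mm)
        errors.append(relative_error(m.size_mm, scene.polyp_diameter_mm))
        return 0
    except (PipelineError, RuntimeError):
        return 1


def run_sensitivity(sweep: str, config: EvalConfig | None = None,
                    seeds=range(20), out_dir=None) -> list[EvaluationRecord]:
    """Run one of the four sensitivity sweeps.

    ``sweep`` is one of ``movement``, ``depth``, ``dsc``, ``noise_scale``.
    Per-trial measurement failures are recorded, not fatal (near-zero
    baselines of type-0 movements are expected to be refused).  Results
    are returned as one record per condition and optionally written as
    CSV + a box plot under ``out_dir``.
    """
    config = config or EvalConfig()
    seeds = list(seeds)
    records: list[EvaluationRecord] = []

    if sweep == "movement":
        for mtype in config.movement_types:
            est, errs, failed = [], [], 0
            for s in seeds:
                scene = sim.make_scene(config.scene_config,
                                       seed=config.base_seed + s)
                rng = np.random.default_rng(10_000 + s)
                depth = rng.uniform(*config.depth_range_mm)
                failed += _sweep_trial(scene, mtype, depth, config.noise,
                                       1000 + s, config.mode, errs, est, None)
            records.append(EvaluationRecord(f"type {mtype}", est, errs, failed))
    elif sweep == "depth":
        for depth in config.depth_grid_mm:
            est, errs, failed = [], [], 0
            for s in seeds:
                scene = sim.make_scene(config.scene_config,
                                       seed=config.base_seed + s)
                failed += _sweep_trial(scene, 1, depth, config.noise,
                                       2000 + s, config.mode, errs, est, None)
            records.append(EvaluationRecord(f"{depth} mm", est, errs, failed))
    elif sweep == "dsc":
        records = _dsc_sweep(config, seeds)
    elif sweep == "noise_scale":
        for mult in config.noise_multipliers:
            noise = config.noise.scaled(mult)
            est, errs, failed = [], [], 0
            for s in seeds:
                scene = sim.make_scene(config.scene_config,
                                       seed=config.base_seed + s)
                rng = np.random.default_rng(30_000 + s)
                depth = rng.uniform(*config.depth_range_mm)
                failed += _sweep_trial(scene, 1, depth, noise,
                                       3000 + s, config.mode, errs, est, None)
            records.append(EvaluationRecord(f"x{mult:g}", est, errs, failed))
    else:
        raise ValueError(f"unknown sweep {sweep!r}")

    if out_dir is not None:
        _write_sweep(records, sweep, out_dir)
    return records


def _dsc_sweep(config: EvalConfig, seeds) -> list[EvaluationRecord]:
    """Segmentation-quality sweep: one noiseless pair, perturbed masks."""
    scene = sim.make_scene(config.scene_config, seed=config.base_seed)
    pose1, pose2 = sim.sample_pose_pair(scene, 1, config.dsc_depth_mm,
                                        seed=config.base_seed + 7)
    obs1, obs2 = sim.make_observation_pair(scene, pose1, pose2, noise=None,
                                           mode="correspondence")
    calib = Calibration(scene.camera, scene.hand_eye)
    truth_mask = sim._ground_truth_mask(scene, pose1)
    records = []
    for target in config.dsc_grid:
        est, errs, failed = [], [], 0
        for i, s in enumerate(seeds):
            mode = "over" if i % 2 == 0 else "under"
            try:
                mask = seg.perturb_mask_to_dsc(truth_mask, target, mode=mode,
                                               seed=4000 + s)
                cfg = PipelineConfig(mask_override=mask)
                m = measure_pair(obs1, obs2, calib, cfg)
                est.append(m.size_mm)
                errs.append(relative_error(m.size_mm,
                                           scene.polyp_diameter_mm))
            except (PipelineError, ValueError, RuntimeError):
                failed += 1
        records.append(EvaluationRecord(f"DSC {target:g}", est, errs, failed))
    return records


def _write_sweep(records: list[EvaluationRecord], sweep: str, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        for e, v in zip(r.errors_pct, r.estimates_mm):
            rows.append({"condition": r.condition, "size_mm": v,
                         "error_pct": e})
    pd.DataFrame(rows).to_csv(out / f"{sweep}.csv", index=False)
    summary = pd.DataFrame([
        {"condition": r.condition, "n": len(r.errors_pct),
         "n_failed": r.n_failed, "mean_error_pct": r.mean_error_pct,
         "sd_error_pct": r.sd_error_pct,
         "median_error_pct": r.median_error_pct}
        for r in records])
    summary.to_csv(out / f"{sweep}_summary.csv", index=False)

    fig, ax = plt.subplots(figsize=(7, 4))
    data = [r.errors_pct if r.errors_pct else [np.nan] for r in records]
    ax.boxplot(data, tick_labels=[r.condition for r in records],
               showmeans=True)
    ax.set_ylabel("size error [%]")
    ax.set_title(f"{sweep} sweep")
    fig.tight_layout()
    fig.savefig(out / f"{sweep}.png", dpi=120)
    plt.close(fig)


def measurement_to_dict(m: PolypMeasurement) -> dict:
    return {
        "size_mm": m.size_mm,
        "depth_mm": m.depth_mm,
        "center_generator_mm": (None if m.center_generator_mm is None
                                else list(map(float, m.center_generator_mm))),
        "distance_to_landmark_mm": m.distance_to_landmark_mm,
        "n_points": m.n_points,
        "rms_residual_mm": m.rms_residual_mm,
        "flags": m.flags,
    }


def write_report(path, measurements: list[PolypMeasurement],
                 final: PolypMeasurement) -> None:
    doc = measurement_to_dict(final)
    doc["n_pairs_used"] = len(measurements)
    doc["per_pair"] = [measurement_to_dict(m) for m in measurements]
    Path(path).write_text(json.dumps(doc, indent=2))
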