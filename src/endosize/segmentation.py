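"""Polyp border segmentation and segmentation-quality utilities.

The polyp is located in the first image of a pair by edge detection on the
V channel of HSV colour space followed by morphological closing, hole
filling and connected-component selection on shape: polyp-like candidates
are compact (low eccentricity) blobs within an area band.  Quality of a
segmentation against a reference is quantified by the Dice similarity
coefficient, and :func:`perturb_mask_to_dsc` manufactures over- or
under-segmentations at a prescribed Dice level for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, feature, measure, morphology

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "segment_polyp",
    "dice",
    "perturb_mask_to_dsc",
    "mask_to_border",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the edge-based polyp segmenter.

    Canny thresholds are hysteresis bounds on the Gaussian-smoothed
    gradient magnitude of the V channel, expressed as quantiles of the
    per-image gradient distribution by default (robust to contrast
    stretching); the area band is a fraction of the image area; ``e_max``
    is the maximum eccentricity of an acceptable candidate (0 = circle).
    """

    canny_low: float = 0.95
    canny_high: float = 0.99
    canny_quantiles: bool = True
    canny_sigma: float = 2.0
    closing_radius: int = 5
    opening_radius: int = 7  # prunes thin protrusions that skew the fitted axis
    e_max: float = 0.85
    area_min_frac: float = 0.002
    area_max_frac: float = 0.60
    max_border_points: int = 400


@dataclass
class SegmentationResult:
    """Mask + ordered border polygon; ``found`` is False when no candidate
    survived the shape filters (callers should fall back to a manual ROI)."""

    mask: np.ndarray | None
    border: np.ndarray | None  # (N, 2) ordered (u, v) pixel coordinates
    found: bool
    eccentricity: float | None = None
    area_px: float | None = None


def _v_channel(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 2:
        v = img.astype(float)
    else:
        v = color.rgb2hsv(img[..., :3])[..., 2] * 255.0
    if img.dtype != np.uint8 and v.max() <= 1.5:
        v = v * 255.0
    return v


def mask_to_border(mask: np.ndarray, max_points: int = 400) -> np.ndarray:
    """Ordered (u, v) border polygon of the largest contour of ``mask``."""
    padded = np.pad(np.asarray(mask, bool), 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask has no border")
    contour = max(contours, key=len) - 1.0  # unpad; (row, col)
    border = contour[:, ::-1]  # -> (u, v)
    if len(border) > max_points:
        idx = np.linspace(0, len(border) - 1, max_points).astype(int)
        border = border[idx]
    return border


def segment_polyp(image: np.ndarray,
                  params: SegmentationParams = SegmentationParams()
                  ) -> SegmentationResult:
    """Locate the polyp region in a colour image.

    Returns a no-find result (``found=False``) rather than raising when no
    region passes the shape filters, so that a pipeline can signal a
    manual-ROI fallback.
    """
    v = _v_channel(image)
    edges = feature.canny(v, sigma=params.canny_sigma,
                          low_threshold=params.canny_low,
                          high_threshold=params.canny_high,
                          use_quantiles=params.canny_quantiles)
    closed = morphology.closing(edges, morphology.disk(params.closing_radius))
    filled = ndimage.binary_fill_holes(closed)
    if params.opening_radius:
        filled = morphology.opening(filled,
                                    morphology.disk(params.opening_radius))
    labels = measure.label(filled)
    area_img = v.shape[0] * v.shape[1]
    best = None
    for region in measure.regionprops(labels):
        frac = region.area / area_img
        if frac < params.area_min_frac or frac > params.area_max_frac:
            continue
        if region.eccentricity > params.e_max:
            continue
        key = (region.eccentricity, -region.area)
        if best is None or key < best[0]:
            best = (key, region)
    if best is None:
        return SegmentationResult(mask=None, border=None, found=False)
    region = best[1]
    mask = labels == region.label
    border = mask_to_border(mask, params.max_border_points)
    return SegmentationResult(mask=mask, border=border, found=True,
                              eccentricity=float(region.eccentricity),
                              area_px=float(region.area))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|a∩b| / (|a|+|b|)``."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("masks differ in shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Dice coefficient undefined for two empty masks")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive outside the mask, negative inside (pixels)."""
    mask = np.asarray(mask, bool)
    outside = ndimage.distance_transform_edt(~mask)
    inside = ndimage.distance_transform_edt(mask)
    return outside - inside


def perturb_mask_to_dsc(mask: np.ndarray, target: float, mode: str = "over",
                        seed: int | None = 0) -> np.ndarray:
    """Degrade a mask to a prescribed Dice similarity against itself.

    ``mode='over'`` grows the region (over-segmentation), ``'under'``
    shrinks it.  A smooth random boundary jitter is superimposed so the
    result is not a pure morphological offset; the offset radius is then
    found by bisection so that ``dice(result, mask)`` lands within 0.01 of
    ``target``.
    """
    mask = np.asarray(mask, bool)
    if not (0.0 < target <= 1.0):
        raise ValueError("target DSC must be in (0, 1]")
    if mask.sum() == 0:
        raise ValueError("cannot perturb an empty mask")
    if mode not in ("over", "under"):
        raise ValueError("mode must be 'over' or 'under'")
    if target == 1.0:
        return mask.copy()

    sd = _signed_distance(mask)
    r_eq = np.sqrt(mask.sum() / np.pi)
    sign = 1.0 if mode == "over" else -1.0
    rng = np.random.default_rng(seed)
    # hand-drawn boundary error model: fine-scale irregularity (correlation
    # length ~ 0.08 r_eq) carries much of the Dice deficit, the rest is a
    # systematic offset found by bisection
    jitter_amp = 0.8 * (1.0 - target) * r_eq

    def carve(radius: float, jitter: np.ndarray) -> np.ndarray:
        return (sd + jitter) <= sign * radius

    # shrink the jitter if by itself it already overshoots the Dice target
    for _ in range(8):
        jitter = ndimage.gaussian_filter(
            rng.standard_normal(mask.shape), sigma=0.08 * r_eq)
        jitter = jitter / max(jitter.std(), 1e-12) * jitter_amp
        if dice(carve(0.0, jitter), mask) > target:
            break
        jitter_amp *= 0.6
    else:
        jitter = np.zeros_like(sd)

    r_max = r_eq if mode == "over" else 0.97 * r_eq
    if dice(carve(r_max, jitter), mask) > target:
        raise ValueError(
            f"target DSC {target} unreachable within radius {r_max:.1f} px")
    lo, hi = 0.0, r_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if dice(carve(mid, jitter), mask) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    result = carve(0.5 * (lo + hi), jitter)
    if result.sum() == 0:
        raise ValueError("perturbation erased the mask entirely")
    return result
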