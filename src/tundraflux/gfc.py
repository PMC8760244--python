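"""Green Fractional Cover (GFC) from nadir collar photographs.

GFC is the ratio of the vertical projection of green, photosynthetic
vegetation to the total ground area inside the collar.  The estimator:

1. adaptive local Wiener low-pass filtering per RGB channel (noise
   reduction);
2. excess-green index g = 2G - B - R per pixel;
3. segmentation of green pixels inside a circular region of interest, either
   at the natural fixed threshold g > 0 or with Otsu's method on the g
   histogram;
4. GFC = green pixel count / ROI pixel count.

Vegetation layering is not modelled, so GFC is bounded in [0, 1]; reddish
plant elements have g < 0 and are excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class CircularRoi:
    """Collar region of interest: centre (cy, cx) and radius, in pixels."""

    cy: float
    cx: float
    radius: float

    def mask(self, shape) -> np.ndarray:
        h, w = shape[:2]
        if (
            self.cy - self.radius < -0.5
            or self.cx - self.radius < -0.5
            or self.cy + self.radius > h - 0.5
            or self.cx + self.radius > w - 0.5
        ):
            raise ValueError("ROI extends outside image bounds")
        yy, xx = np.mgrid[0:h, 0:w]
        return (yy - self.cy) ** 2 + (xx - self.cx) ** 2 <= self.radius**2


@dataclass
class GfcResult:
    gfc: float
    green_pixels: int
    roi_pixels: int
    mask: np.ndarray


def default_roi(shape) -> CircularRoi:
    """Centred collar ROI covering 90% of the shorter image side."""
    h, w = shape[:2]
    return CircularRoi(cy=(h - 1) / 2.0, cx=(w - 1) / 2.0, radius=0.45 * min(h, w))


def denoise(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Adaptive local Wiener low-pass filter, applied per channel.

    Pixelwise: out = m + max(0, 1 - nu/s2) (x - m), with m and s2 the local
    mean and variance over a window x window neighbourhood (reflective
    boundaries) and nu the noise power, estimated as the mean of the local
    variances.  Flat regions collapse to their local mean, high-variance
    structure passes through; a constant image is unchanged and window = 1
    is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    img = np.asarray(image, dtype=float)
    if window == 1:
        return img.copy()

    def _wiener2(chan: np.ndarray) -> np.ndarray:
        m = uniform_filter(chan, window, mode="reflect")
        s2 = uniform_filter(chan * chan, window, mode="reflect") - m * m
        s2 = np.maximum(s2, 0.0)
        nu = s2.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = np.where(s2 > nu, 1.0 - nu / np.where(s2 > 0, s2, 1.0), 0.0)
        return m + gain * (chan - m)

    if img.ndim == 2:
        return _wiener2(img)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = _wiener2(img[..., c])
    return out


def greenness_index(image: np.ndarray) -> np.ndarray:
    """Excess-green index g = 2G - B - R, signed, per pixel."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {img.shape}")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    return 2.0 * g - b - r


def segment_green(g_map: np.ndarray, roi: CircularRoi, threshold_mode: str = "fixed_zero") -> np.ndarray:
    """Binary green mask inside the collar ROI.

    threshold_mode 'fixed_zero' keeps pixels with g > 0 (the natural
    background boundary of an excess-green index); 'otsu_on_g' thresholds the
    within-ROI g histogram with Otsu's method.
    """
    g_map = np.asarray(g_map, dtype=float)
    roi_mask = roi.mask(g_map.shape)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    if threshold_mode == "fixed_zero":
        thr = 0.0
    elif threshold_mode == "otsu_on_g":
        inside = g_map[roi_mask]
        if np.ptp(inside) == 0:
            return np.zeros_like(roi_mask)
        thr = threshold_otsu(inside)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return (g_map > thr) & roi_mask


def compute_gfc(mask: np.ndarray, roi: CircularRoi) -> GfcResult:
    """GFC = green pixel count / ROI pixel count."""
    mask = np.asarray(mask, dtype=bool)
    roi_mask = roi.mask(mask.shape)
    roi_pixels = int(roi_mask.sum())
    if roi_pixels == 0:
        raise ValueError("ROI contains no pixels")
    green = int((mask & roi_mask).sum())
    return GfcResult(gfc=green / roi_pixels, green_pixels=green, roi_pixels=roi_pixels, mask=mask & roi_mask)


def estimate_gfc(
    image: np.ndarray,
    roi: CircularRoi | None = None,
    threshold_mode: str = "fixed_zero",
    wiener_window: int = 5,
) -> GfcResult:
    """Full pipeline: denoise -> greenness index -> segment -> ratio."""
    if roi is None:
        roi = default_roi(np.asarray(image).shape)
    filtered = denoise(image, wiener_window)
    g = greenness_index(filtered)
    mask = segment_green(g, roi, threshold_mode)
    return compute_gfc(mask, roi)
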