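"""Laser-pair scale calibration for texture imagery.

Two parallel underwater lasers hold a fixed 10 cm beam separation
regardless of camera-to-subject distance, so the pixel distance between
the two dots in a photograph calibrates a mm-per-pixel scale for that
image.  Detection thresholds a weighted-channel map (green-dominant by
default) at a high quantile, labels connected components, and takes the
intensity-weighted centroid of the two blobs.  When the laser pair is
unavailable, a reference object of known physical length provides the
same calibration.  Scale-bar annotations are emitted as sidecar
records; source pixels are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

__all__ = [
    "DotDetectionError",
    "LaserCalibration",
    "detect_laser_dots",
    "mm_per_pixel",
    "scalebar_pixels",
]

DEFAULT_SEPARATION_MM = 100.0  # fixed 10 cm beam separation
DEFAULT_BAR_LENGTH_MM = 20.0


class DotDetectionError(RuntimeError):
    """Raised when thresholding does not yield exactly two laser blobs."""

    def __init__(self, n_candidates: int):
        self.n_candidates = n_candidates
        super().__init__(
            f"expected exactly 2 laser-dot candidates, found {n_candidates}"
        )


@dataclass(frozen=True)
class LaserCalibration:
    """A pixel-to-millimeter scale derived for one image.

    ``centroid_1``/``centroid_2`` are sub-pixel (row, col) coordinates;
    ``separation_mm`` the known physical distance they subtend.
    """

    centroid_1: tuple[float, float]
    centroid_2: tuple[float, float]
    separation_mm: float = DEFAULT_SEPARATION_MM
    method: str = "laser_pair"

    def __post_init__(self):
        if self.separation_mm <= 0:
            raise ValueError("separation_mm must be positive")
        if self.method not in ("laser_pair", "reference_object"):
            raise ValueError("method must be 'laser_pair' or 'reference_object'")

    @property
    def pixel_distance(self) -> float:
        d = np.hypot(
            self.centroid_1[0] - self.centroid_2[0],
            self.centroid_1[1] - self.centroid_2[1],
        )
        return float(d)

    @classmethod
    def from_image(
        cls,
        image: np.ndarray,
        separation_mm: float = DEFAULT_SEPARATION_MM,
        **detect_kwargs,
    ) -> "LaserCalibration":
        c1, c2 = detect_laser_dots(image, **detect_kwargs)
        return cls(c1, c2, separation_mm, "laser_pair")

    @classmethod
    def from_reference_object(
        cls, pixel_span: float, known_mm: float
    ) -> "LaserCalibration":
        """Fallback calibration from an object of known physical length
        measured as ``pixel_span`` pixels in the image."""
        if pixel_span <= 0:
            raise ValueError("pixel_span must be positive")
        return cls((0.0, 0.0), (0.0, float(pixel_span)), known_mm, "reference_object")


def detect_laser_dots(
    image: np.ndarray,
    channel_weights=(-0.5, 1.0, -0.5),
    threshold_quantile: float = 0.999,
    min_area_px: int = 3,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Locate the two laser dots at sub-pixel precision.

    The image is collapsed to a single map with ``channel_weights``
    (default: green excess over the mean of red and blue, matching
    green lasers on a roughly neutral scene), thresholded at
    ``threshold_quantile`` of the map's values, and connected components
    of at least ``min_area_px`` pixels are kept as candidates.  The two
    largest candidates — by integrated above-threshold intensity, which
    separates intense laser blobs from broad low-contrast texture
    maxima — provide intensity-weighted centroids.  Fewer than two
    candidates raises :class:`DotDetectionError` with the candidate
    count (callers may fall back to
    :meth:`LaserCalibration.from_reference_object`).  Quantile
    thresholding and excess weighting make the result invariant to any
    uniform background offset.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        weighted = image @ np.asarray(channel_weights, dtype=float)
    else:
        weighted = image
    thr = float(np.quantile(weighted, threshold_quantile))
    binary = weighted > thr
    labels = label(binary)
    excess = np.clip(weighted - thr, 0.0, None)
    regions = [r for r in regionprops(labels) if r.area >= min_area_px]
    if len(regions) < 2:
        raise DotDetectionError(len(regions))
    masses = [float(excess[labels == r.label].sum()) for r in regions]
    keep = np.argsort(masses)[-2:]

    centroids = []
    for i in keep:
        mask = labels == regions[i].label
        yy, xx = np.nonzero(mask)
        w = excess[yy, xx]
        total = w.sum()
        centroids.append((float((w * yy).sum() / total), float((w * xx).sum() / total)))
    # deterministic ordering: left-to-right, then top-to-bottom
    centroids.sort(key=lambda c: (c[1], c[0]))
    return centroids[0], centroids[1]


def mm_per_pixel(calib: LaserCalibration) -> float:
    """Physical scale of the image: known separation over pixel distance."""
    d = calib.pixel_distance
    if d < 1e-9:
        raise ValueError("centroids are coincident; cannot derive a scale")
    return calib.separation_mm / d


def scalebar_pixels(
    mm_per_px: float,
    bar_length_mm: float = DEFAULT_BAR_LENGTH_MM,
    position: tuple[int, int] = (20, 20),
) -> tuple[int, dict]:
    """Pixel length of a physical scale bar, plus a sidecar annotation.

    The bar length is ``bar_length_mm / mm_per_px`` rounded to the
    nearest integer pixel.  The annotation records placement and scale;
    drawing is left to the caller so source pixels stay untouched.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    if bar_length_mm <= 0:
        raise ValueError("bar length must be positive")
    length_px = int(round(bar_length_mm / mm_per_px))
    annotation = {
        "bar_length_mm": bar_length_mm,
        "mm_per_px": mm_per_px,
        "length_px": length_px,
        "position_rc": list(position),
    }
    return length_px, annotation
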