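"""Perceptual hue/chroma analysis of color-card measurements.

Panel colors measured at each depth are converted from linear RGB to
CIELAB, and the set of panel colors at one depth is summarised as a
convex "gamut polygon" in the (a, b) opponent-color plane.  The
shrinkage and drift of these polygons with depth quantifies how the
water column strips long-wavelength (red/orange) information, which is
the light environment a nocturnal reef cuttlefish's skin colors are —
or are not — visible in.

Conversions assume sRGB primaries and the D65 white point; camera RGB
from a raw decode with white balance off is treated as an sRGB dialect
(see the colorimetry section of the methods documentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "HueChromaPoint",
    "GamutPolygon",
    "linear_rgb_to_xyz",
    "xyz_to_lab",
    "linear_rgb_to_lab",
    "srgb_to_linear",
    "linear_to_srgb",
    "rgb_to_hue_chroma",
    "hue_chroma_points",
    "gamut_polygon",
    "shoelace_area",
    "depth_gamut_profile",
]

# sRGB (IEC 61966-2-1) primaries -> CIE XYZ, D65 white, 2-degree observer.
_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# Reference white is the matrix image of RGB (1,1,1), so a pure neutral
# maps to a = b = 0 exactly rather than to within matrix rounding.
_WHITE = _RGB2XYZ @ np.ones(3)

#: Chroma below which the hue angle is numerically meaningless.
CHROMA_TOLERANCE = 1e-6


@dataclass(frozen=True)
class HueChromaPoint:
    """One color expressed in CIELAB cylindrical coordinates.

    ``hue`` is the angle of (a, b) in degrees mapped to [0, 360);
    ``chroma`` is sqrt(a^2 + b^2) (a.u.).  For near-neutral colors the
    hue angle is undefined and ``hue_defined`` is False (``hue`` is 0.0).
    """

    hue: float
    chroma: float
    L: float
    hue_defined: bool = True
    panel_id: str | None = None
    depth: float | None = None

    @property
    def ab(self) -> tuple[float, float]:
        h = np.deg2rad(self.hue)
        return (self.chroma * np.cos(h), self.chroma * np.sin(h))


@dataclass(frozen=True)
class GamutPolygon:
    """Convex hull of one depth's panel colors in the (a, b) plane."""

    depth: float | None
    vertices: np.ndarray  # (m, 2) counter-clockwise (a, b) coordinates
    area: float  # squared-chroma units
    degenerate: bool = False  # point or segment: area is exactly 0

    @property
    def hue_chroma_vertices(self) -> np.ndarray:
        """Polar rendering of the hull vertices: columns (hue_deg, chroma)."""
        a, b = self.vertices[:, 0], self.vertices[:, 1]
        hue = np.rad2deg(np.arctan2(b, a)) % 360.0
        return np.column_stack([hue, np.hypot(a, b)])


def srgb_to_linear(v: np.ndarray) -> np.ndarray:
    """Invert the sRGB transfer function (for gamma-encoded 8-bit input)."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(v: np.ndarray) -> np.ndarray:
    """Apply the sRGB transfer function to linear intensities."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


def _check_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("expected an array with 3 color channels on the last axis")
    if np.any(rgb < -1e-9) or np.any(rgb > 1 + 1e-9):
        raise ValueError("linear RGB values must lie in [0, 1]")
    return np.clip(rgb, 0.0, 1.0)


def linear_rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Linear RGB (sRGB primaries) -> CIE XYZ, vectorised over leading axes."""
    return _check_rgb(rgb) @ _RGB2XYZ.T


def xyz_to_lab(xyz: np.ndarray) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    t = xyz / _WHITE
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def linear_rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Linear RGB in [0,1] -> CIELAB (L in [0,100], a/b opponent axes)."""
    return xyz_to_lab(linear_rgb_to_xyz(rgb))


def rgb_to_hue_chroma(
    color: np.ndarray,
    *,
    panel_id: str | None = None,
    depth: float | None = None,
    chroma_tolerance: float = CHROMA_TOLERANCE,
) -> HueChromaPoint:
    """Convert one linear-RGB color to a CIELAB hue/chroma point.

    Raises ``ValueError`` for out-of-range input.  Hue is flagged
    undefined when chroma falls below ``chroma_tolerance``.
    """
    color = np.asarray(color, dtype=float)
    if color.shape != (3,):
        raise ValueError("rgb_to_hue_chroma expects a single (3,) color")
    L, a, b = linear_rgb_to_lab(color)
    chroma = float(np.hypot(a, b))
    if chroma < chroma_tolerance:
        return HueChromaPoint(0.0, chroma, float(L), False, panel_id, depth)
    hue = float(np.rad2deg(np.arctan2(b, a)) % 360.0)
    return HueChromaPoint(hue, chroma, float(L), True, panel_id, depth)


def hue_chroma_points(
    colors: np.ndarray,
    *,
    panel_ids: list[str] | None = None,
    depth: float | None = None,
) -> list[HueChromaPoint]:
    """Vector convenience wrapper over :func:`rgb_to_hue_chroma`."""
    colors = np.atleast_2d(np.asarray(colors, dtype=float))
    ids = panel_ids if panel_ids is not None else [None] * len(colors)
    return [
        rgb_to_hue_chroma(c, panel_id=i, depth=depth) for c, i in zip(colors, ids)
    ]


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area from ordered vertices via the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def gamut_polygon(points: np.ndarray, depth: float | None = None) -> GamutPolygon:
    """Convex hull of (a, b)-plane points for one depth.

    ``points`` is an (n, 2) array of CIELAB (a, b) coordinates (or a list
    of :class:`HueChromaPoint`).  Degenerate inputs (a single point, or
    collinear points) return a flagged polygon with area 0.
    """
    if isinstance(points, (list, tuple)) and points and isinstance(points[0], HueChromaPoint):
        points = np.array([p.ab for p in points])
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("gamut_polygon requires at least one point")
    if pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) in the (a, b) plane")
    if len(pts) < 3:
        return GamutPolygon(depth, np.unique(pts, axis=0), 0.0, degenerate=True)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # Collinear set: report the extreme segment endpoints.
        d = pts - pts.mean(axis=0)
        axis = d[np.argmax(np.linalg.norm(d, axis=1))]
        if np.linalg.norm(axis) == 0:
            return GamutPolygon(depth, pts[:1], 0.0, degenerate=True)
        proj = d @ axis
        seg = pts[[np.argmin(proj), np.argmax(proj)]]
        return GamutPolygon(depth, seg, 0.0, degenerate=True)
    verts = pts[hull.vertices]  # counter-clockwise in 2-D
    return GamutPolygon(depth, verts, shoelace_area(verts), degenerate=False)


def depth_gamut_profile(series, sightings=None) -> pd.DataFrame:
    """Per-depth gamut summary table with sighting-depth overlay.

    Parameters
    ----------
    series:
        A :class:`~cuttlefield.colorcard.ColorCardSeries` (panel colors per
        measured depth, linear RGB).
    sightings:
        Optional animal sightings: a DataFrame with a ``depth_m`` column,
        or a plain sequence of depths in meters.  Each sighting is
        assigned to the measured depth whose half-open bin (bounded by
        midpoints between consecutive measured depths) contains it.

    Returns one row per measured depth: hue and chroma ranges over
    panels with defined hue, the (a, b) hull area, and the overlaid
    sighting depths.
    """
    depths = np.asarray(series.depths, dtype=float)
    if sightings is None:
        s_depths = np.array([])
    elif hasattr(sightings, "columns"):
        s_depths = np.asarray(sightings["depth_m"], dtype=float)
    else:
        s_depths = np.asarray(sightings, dtype=float)

    # Half-open row bins [lo_i, hi_i) bounded by midpoints between depths.
    mids = (depths[:-1] + depths[1:]) / 2.0
    lo = np.concatenate([[-np.inf], mids])
    hi = np.concatenate([mids, [np.inf]])

    rows = []
    for i, z in enumerate(depths):
        lab = linear_rgb_to_lab(series.colors[i])
        ab = lab[:, 1:3]
        poly = gamut_polygon(ab, depth=z)
        chroma = np.hypot(ab[:, 0], ab[:, 1])
        defined = chroma >= CHROMA_TOLERANCE
        hue = np.rad2deg(np.arctan2(ab[defined, 1], ab[defined, 0])) % 360.0
        in_row = s_depths[(s_depths >= lo[i]) & (s_depths < hi[i])]
        rows.append(
            {
                "depth_m": z,
                "n_panels": series.colors.shape[1],
                "hue_min_deg": float(hue.min()) if hue.size else np.nan,
                "hue_max_deg": float(hue.max()) if hue.size else np.nan,
                "chroma_min": float(chroma.min()),
                "chroma_max": float(chroma.max()),
                "area_ab": poly.area,
                "n_sightings": int(in_row.size),
                "sighting_depths_m": ";".join(f"{d:g}" for d in sorted(in_row)),
            }
        )
    return pd.DataFrame(rows)
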