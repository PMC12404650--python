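"""Panel-color extraction and per-channel attenuation-model fitting.

The color chart photographed at a series of depths yields, for every
panel, a per-channel intensity that decays with depth as longer
wavelengths are absorbed by the water column.  The default model is
Beer–Lambert: ``I_c(z) = I_c(0) * exp(-k_c * z)`` with one diffuse
attenuation coefficient ``k_c`` per camera channel, fitted by ordinary
least squares on log-intensity pooled over the chosen panels (each
panel keeps its own intercept — its fitted surface intensity).  A
piecewise-linear empirical interpolation of the measured per-channel
ratios is available as an alternative mode for users who prefer not to
impose a functional form between stations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import CardLayout

__all__ = [
    "DARK_FLOOR",
    "ColorCardSeries",
    "AttenuationModel",
    "extract_panel_colors",
    "fit_attenuation",
    "predict_channel_scale",
]

#: Intensities at or below this linear value (one 8-bit quantization
#: step) are excluded from the log-domain fit: below sensor
#: quantization, log-intensity carries no information.
DARK_FLOOR = 1.0 / 255.0

_CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class ColorCardSeries:
    """Mean linear-RGB color of every chart panel at each depth.

    ``depths`` is sorted non-decreasing (near-duplicate stations such as
    11.7 and 11.8 m are kept as independent rows); ``colors`` has shape
    (n_depths, n_panels, 3) with values in [0, 1].
    """

    depths: np.ndarray
    colors: np.ndarray
    panel_ids: tuple[str, ...]
    neutral_panel_ids: tuple[str, ...] = ()

    def __post_init__(self):
        depths = np.asarray(self.depths, dtype=float)
        colors = np.asarray(self.colors, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "colors", colors)
        if depths.ndim != 1 or colors.shape != (len(depths), len(self.panel_ids), 3):
            raise ValueError("colors must have shape (n_depths, n_panels, 3)")
        if np.any(np.diff(depths) < 0):
            raise ValueError("depths must be sorted non-decreasing")
        if np.any(colors < -1e-9) or np.any(colors > 1 + 1e-9):
            raise ValueError("panel colors must lie in [0, 1]")

    def panel_index(self, panel_id: str) -> int:
        return self.panel_ids.index(panel_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: depth_m, panel_id, R, G, B."""
        rows = []
        for z, panel_colors in zip(self.depths, self.colors):
            for pid, c in zip(self.panel_ids, panel_colors):
                rows.append({"depth_m": z, "panel_id": pid,
                             "R": c[0], "G": c[1], "B": c[2],
                             "neutral": pid in self.neutral_panel_ids})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ColorCardSeries":
        frame = frame.sort_values(["depth_m"], kind="stable")
        depths = np.array(sorted(frame["depth_m"].unique()))
        panel_ids = tuple(frame["panel_id"].unique())
        colors = np.empty((len(depths), len(panel_ids), 3))
        for i, z in enumerate(depths):
            sub = frame[frame["depth_m"] == z].set_index("panel_id")
            colors[i] = sub.loc[list(panel_ids), ["R", "G", "B"]].to_numpy()
        neutral = ()
        if "neutral" in frame.columns:
            neutral = tuple(frame.loc[frame["neutral"], "panel_id"].unique())
        return cls(depths, colors, panel_ids, neutral)


@dataclass(frozen=True)
class AttenuationModel:
    """Fitted per-channel water-column attenuation.

    ``k`` holds one coefficient per channel (1/m; NaN where a channel
    could not be fitted); ``surface_color`` the fitted z = 0 intensity
    of each fit panel.  ``rmse_log`` is the per-channel residual RMSE in
    log-intensity units and ``n_excluded`` the number of points dropped
    at the dark floor.  ``knot_depths``/``knot_scales`` carry the
    measured per-channel intensity ratios used by the piecewise-linear
    interpolation mode.
    """

    k: np.ndarray
    surface_color: np.ndarray
    panel_ids: tuple[str, ...]
    rmse_log: np.ndarray
    n_excluded: np.ndarray
    channel_ok: np.ndarray
    interpolation_mode: str = "exponential"
    knot_depths: np.ndarray | None = None
    knot_scales: np.ndarray | None = None
    negative_k: bool = False

    def __post_init__(self):
        if self.interpolation_mode not in ("exponential", "piecewise-linear"):
            raise ValueError("interpolation_mode must be 'exponential' or 'piecewise-linear'")
        if self.interpolation_mode == "piecewise-linear" and self.knot_depths is None:
            raise ValueError("piecewise-linear mode requires measured knots")

    @classmethod
    def from_coefficients(cls, k, surface_color=None) -> "AttenuationModel":
        """Construct an exponential model directly from known coefficients."""
        k = np.asarray(k, dtype=float)
        sc = np.atleast_2d(np.ones(3) if surface_color is None else surface_color)
        return cls(
            k=k,
            surface_color=sc,
            panel_ids=tuple(f"P{i:02d}" for i in range(len(sc))),
            rmse_log=np.zeros(3),
            n_excluded=np.zeros(3, dtype=int),
            channel_ok=np.isfinite(k),
        )


def extract_panel_colors(image: np.ndarray, layout: CardLayout) -> np.ndarray:
    """Arithmetic mean linear intensity over each panel region.

    Returns an (n_panels, 3) array.  Regions outside the image or with
    zero area are rejected.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[..., None].repeat(3, axis=-1)
    h, w = image.shape[:2]
    means = np.empty((len(layout.panels), 3))
    for i, panel in enumerate(layout.panels):
        r0, c0, r1, c1 = panel.region
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"panel {panel.panel_id} has a zero-area region")
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(f"panel {panel.panel_id} region lies outside the image")
        means[i] = image[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0)
    return means


def _fit_channel(depths, intensities, floor):
    """Pooled log-linear OLS with per-panel intercepts for one channel.

    ``intensities`` is (n_depths, n_panels).  Returns
    (k, log_intercepts, rmse, n_excluded, ok).  Panels with no usable
    point get a NaN intercept; the slope uses within-panel demeaning, so
    single-point panels contribute an intercept but no slope
    information.
    """
    n_depths, n_panels = intensities.shape
    usable = intensities > floor
    n_excluded = int((~usable).sum())
    if np.unique(depths[usable.any(axis=1)]).size < 3:
        return np.nan, np.full(n_panels, np.nan), np.nan, n_excluded, False

    z_parts, y_parts = [], []
    panel_means = np.full((n_panels, 2), np.nan)  # (mean z, mean log I)
    for p in range(n_panels):
        m = usable[:, p]
        if not m.any():
            continue
        z = depths[m]
        y = np.log(intensities[m, p])
        panel_means[p] = (z.mean(), y.mean())
        z_parts.append(z - z.mean())
        y_parts.append(y - y.mean())
    zt = np.concatenate(z_parts)
    yt = np.concatenate(y_parts)
    denom = float(zt @ zt)
    slope = float(zt @ yt) / denom if denom > 0 else 0.0
    k = -slope
    intercepts = panel_means[:, 1] - slope * panel_means[:, 0]
    resid = yt - slope * zt
    rmse = float(np.sqrt(np.mean(resid**2))) if len(resid) else 0.0
    return k, intercepts, rmse, n_excluded, True


def fit_attenuation(
    series: ColorCardSeries,
    panels_for_fit=None,
    floor: float = DARK_FLOOR,
    interpolation_mode: str = "exponential",
) -> AttenuationModel:
    """Fit the per-channel attenuation model to a measured card series.

    Parameters
    ----------
    series:
        Panel colors per depth (>= 3 distinct depths required).
    panels_for_fit:
        Panel ids to pool in the fit.  Defaults to the neutral ramp when
        the series knows its neutral panels (neutral panels isolate the
        illuminant change from panel chromaticity), otherwise all panels.
    floor:
        Dark floor; intensities <= ``floor`` are excluded from the log
        fit and counted in ``n_excluded``.
    interpolation_mode:
        'exponential' (Beer–Lambert coefficients) or 'piecewise-linear'
        (empirical per-depth intensity ratios used at prediction time).

    A channel with fewer than 3 usable distinct depths is flagged unfit
    (``k`` = NaN).  A series that is entirely at or below the dark floor
    raises ``ValueError``.  Negative fitted coefficients are permitted
    but set the ``negative_k`` warning flag (and emit a warning).
    """
    if panels_for_fit is None:
        panels_for_fit = series.neutral_panel_ids or series.panel_ids
    idx = [series.panel_index(p) for p in panels_for_fit]
    if np.unique(series.depths).size < 3:
        raise ValueError("fit_attenuation requires at least 3 distinct depths")
    sub = series.colors[:, idx, :]  # (n_depths, n_sel, 3)
    shallowest = sub[0]
    if np.any(shallowest.max(axis=1) <= 0):
        # guard against panels that are dark already at the surface
        raise ValueError("selected panels must be non-dark at the shallowest depth")
    if np.all(sub <= floor):
        raise ValueError("series is entirely below the dark floor; nothing to fit")

    k = np.empty(3)
    intercepts = np.empty((len(idx), 3))
    rmse = np.empty(3)
    n_exc = np.empty(3, dtype=int)
    ok = np.empty(3, dtype=bool)
    for c in range(3):
        k[c], intercepts[:, c], rmse[c], n_exc[c], ok[c] = _fit_channel(
            series.depths, sub[:, :, c], floor
        )
    negative = bool(np.any(k[ok] < 0))
    if negative:
        warnings.warn("fitted a negative attenuation coefficient", stacklevel=2)

    knot_depths = knot_scales = None
    if interpolation_mode == "piecewise-linear":
        # measured mean per-channel intensity ratio relative to the
        # shallowest station, over fit panels with a bright surface value
        ref = sub[0]  # (n_sel, 3)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(ref > floor, sub / ref, np.nan)
        knot_depths = series.depths.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            knot_scales = np.nanmean(ratios, axis=1)  # (n_depths, 3)

    return AttenuationModel(
        k=k,
        surface_color=np.exp(intercepts),
        panel_ids=tuple(panels_for_fit),
        rmse_log=rmse,
        n_excluded=n_exc,
        channel_ok=ok,
        interpolation_mode=interpolation_mode,
        knot_depths=knot_depths,
        knot_scales=knot_scales,
        negative_k=negative,
    )


def predict_channel_scale(model: AttenuationModel, depth) -> np.ndarray:
    """Multiplicative per-channel scale of ambient light at ``depth``.

    Exponential mode returns ``exp(-k_c * z)`` (exactly 1 at z = 0);
    piecewise-linear mode interpolates the measured ratios between the
    bracketing stations and clamps outside the measured range.  Accepts
    a scalar or an array of depths; negative depths are rejected.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    if model.interpolation_mode == "exponential":
        return np.exp(-np.multiply.outer(depth, model.k))
    scales = np.stack(
        [
            np.interp(depth, model.knot_depths, model.knot_scales[:, c])
            for c in range(3)
        ],
        axis=-1,
    )
    return scales
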