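"""Synthetic inputs for every pipeline stage.

Three generators emulate the field data the pipeline consumes, with
known ground truth so each downstream stage can be validated by
round-trip recovery:

* a waterproof color card photographed at a series of depths under
  Beer–Lambert per-channel attenuation of downwelling sunlight (with an
  optional full-spectrum flash variant),
* multi-searcher dive logs (depth sampled every 10 s) with effort
  stratified by habitat (reef/muck) and diel period (day/night) and
  encounters drawn from a Poisson process at a stated true rate,
* macro "texture" scenes carrying two parallel green laser dots with a
  known physical separation, for scale calibration.
"""

from __future__ import annotations

import colorsys
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SURVEY_DEPTHS_M",
    "DEFAULT_ATTENUATION_PER_M",
    "WaterOpticsParams",
    "CardPanel",
    "CardLayout",
    "StratumSpec",
    "EffortSpec",
    "ambient_panel_colors",
    "render_card_series",
    "render_card_image",
    "simulate_dive_logs",
    "render_laser_scene",
]

#: Depth grid of the field color-card series: 11 stations from the
#: surface to 25.7 m (two nearly coincident at 11.7/11.8 m).
SURVEY_DEPTHS_M: tuple[float, ...] = (
    0.0, 4.6, 6.0, 11.7, 11.8, 14.0, 17.2, 19.4, 21.1, 22.2, 25.7,
)

#: Default diffuse attenuation coefficients (1/m) for the three broad
#: camera channels in clear tropical water.  Red decays fastest: at 7 m
#: only ~3% of surface red remains, matching the rapid red loss seen in
#: shallow reef photography.
DEFAULT_ATTENUATION_PER_M: tuple[float, float, float] = (0.5, 0.07, 0.04)


@dataclass(frozen=True)
class WaterOpticsParams:
    """Broadband water-column optics for ambient-light rendering.

    Attributes
    ----------
    k:
        Per-channel (R, G, B) attenuation coefficient, 1/m, all >= 0.
    surface_illuminant:
        Relative downwelling intensity per channel at depth 0, in (0, 1].
    noise_sd:
        Standard deviation of additive Gaussian noise in linear units.
    """

    k: tuple[float, float, float] = DEFAULT_ATTENUATION_PER_M
    surface_illuminant: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0

    def __post_init__(self):
        k = np.asarray(self.k, dtype=float)
        ill = np.asarray(self.surface_illuminant, dtype=float)
        if k.shape != (3,) or ill.shape != (3,):
            raise ValueError("k and surface_illuminant must each have 3 channels")
        if np.any(k < 0):
            raise ValueError("attenuation coefficients must be non-negative")
        if np.any(ill <= 0) or np.any(ill > 1):
            raise ValueError("surface_illuminant components must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CardPanel:
    """One chart panel: id, surface reflectance, and pixel region.

    ``region`` is (row0, col0, row1, col1), half-open, image coordinates.
    """

    panel_id: str
    reflectance: tuple[float, float, float]
    region: tuple[int, int, int, int]

    @property
    def is_neutral(self) -> bool:
        r = self.reflectance
        return abs(r[0] - r[1]) < 1e-9 and abs(r[1] - r[2]) < 1e-9


def _default_panels(panel_px: int, gap_px: int) -> list[CardPanel]:
    """24 panels on a 4x6 grid: 18 hues around the circle + 6-step
    neutral ramp (bright-to-mid grays typical of a dive slate chart)."""
    reflectances: list[tuple[float, float, float]] = []
    for i in range(18):
        reflectances.append(colorsys.hsv_to_rgb(i / 18.0, 0.85, 0.80))
    reflectances += [(v, v, v) for v in (0.95, 0.80, 0.65, 0.50, 0.35, 0.20)]
    panels = []
    for idx, refl in enumerate(reflectances):
        r, c = divmod(idx, 6)
        row0 = gap_px + r * (panel_px + gap_px)
        col0 = gap_px + c * (panel_px + gap_px)
        panels.append(
            CardPanel(f"P{idx:02d}", tuple(round(x, 6) for x in refl),
                      (row0, col0, row0 + panel_px, col0 + panel_px))
        )
    return panels


@dataclass(frozen=True)
class CardLayout:
    """Ordered panel inventory of a synthetic color chart."""

    panels: tuple[CardPanel, ...]

    def __post_init__(self):
        if len(self.panels) < 2:
            raise ValueError("a card layout needs at least 2 panels")
        if not any(p.is_neutral for p in self.panels):
            raise ValueError("a card layout needs at least one neutral panel")
        regions = [p.region for p in self.panels]
        for i, a in enumerate(regions):
            if a[0] >= a[2] or a[1] >= a[3]:
                raise ValueError(f"panel {self.panels[i].panel_id} has empty region")
            for b in regions[i + 1:]:
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise ValueError("panel regions overlap")

    @classmethod
    def default(cls, panel_px: int = 40, gap_px: int = 8) -> "CardLayout":
        return cls(tuple(_default_panels(panel_px, gap_px)))

    @property
    def panel_ids(self) -> tuple[str, ...]:
        return tuple(p.panel_id for p in self.panels)

    @property
    def neutral_panel_ids(self) -> tuple[str, ...]:
        return tuple(p.panel_id for p in self.panels if p.is_neutral)

    @property
    def reflectances(self) -> np.ndarray:
        return np.array([p.reflectance for p in self.panels])

    @property
    def image_shape(self) -> tuple[int, int]:
        rows = max(p.region[2] for p in self.panels)
        cols = max(p.region[3] for p in self.panels)
        # symmetric margin equal to the minimal top-left offset
        r0 = min(p.region[0] for p in self.panels)
        c0 = min(p.region[1] for p in self.panels)
        return rows + r0, cols + c0


def ambient_panel_colors(
    optics: WaterOpticsParams, layout: CardLayout, depth: float, flash: bool = False
) -> np.ndarray:
    """Noise-free panel colors (n_panels, 3) at one depth.

    Ambient: reflectance * illuminant * exp(-k z).  Flash: the camera
    supplies full-spectrum light over a negligible water path, so the
    depth term is omitted.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    refl = layout.reflectances
    ill = np.asarray(optics.surface_illuminant)
    if flash:
        return refl * ill
    return refl * ill * np.exp(-np.asarray(optics.k) * depth)


def render_card_series(
    optics: WaterOpticsParams,
    layout: CardLayout | None = None,
    depths=SURVEY_DEPTHS_M,
    flash: bool = False,
    rng: np.random.Generator | int | None = None,
):
    """Render the per-depth panel-color table the card pipeline ingests.

    Returns a :class:`~cuttlefield.colorcard.ColorCardSeries` whose panel
    colors follow the Beer–Lambert rendering rule plus additive Gaussian
    noise of sd ``optics.noise_sd``, clipped to [0, 1].  Depths are
    sorted non-decreasing; duplicates are allowed.
    """
    from .colorcard import ColorCardSeries  # local import to avoid a cycle

    layout = layout or CardLayout.default()
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("depth list must be non-empty")
    if np.any(depths < 0):
        raise ValueError("depths must be non-negative")
    depths = np.sort(depths, kind="stable")
    rng = np.random.default_rng(rng)
    colors = np.stack(
        [ambient_panel_colors(optics, layout, z, flash=flash) for z in depths]
    )
    if optics.noise_sd > 0:
        colors = colors + rng.normal(0.0, optics.noise_sd, size=colors.shape)
    colors = np.clip(colors, 0.0, 1.0)
    return ColorCardSeries(
        depths=depths,
        colors=colors,
        panel_ids=layout.panel_ids,
        neutral_panel_ids=layout.neutral_panel_ids,
    )


def render_card_image(
    optics: WaterOpticsParams,
    layout: CardLayout | None = None,
    depth: float = 0.0,
    flash: bool = False,
    rng: np.random.Generator | int | None = None,
    background: float = 0.05,
) -> np.ndarray:
    """Raster render of the chart at one depth (linear RGB, float, [0,1]).

    Per-pixel additive noise of sd ``optics.noise_sd``; panel regions are
    filled with the same rendering rule as :func:`render_card_series`.
    """
    layout = layout or CardLayout.default()
    rng = np.random.default_rng(rng)
    shape = layout.image_shape
    # the background is a neutral surface and obeys the same lighting rule
    ill = np.asarray(optics.surface_illuminant)
    bg = background * ill
    if not flash:
        bg = bg * np.exp(-np.asarray(optics.k) * depth)
    img = np.broadcast_to(bg, shape + (3,)).astype(float).copy()
    colors = ambient_panel_colors(optics, layout, depth, flash=flash)
    for panel, color in zip(layout.panels, colors):
        r0, c0, r1, c1 = panel.region
        img[r0:r1, c0:c1] = color
    if optics.noise_sd > 0:
        img = img + rng.normal(0.0, optics.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Dive logs and encounters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumSpec:
    """One effort stratum: habitat x diel cell with a true encounter rate."""

    habitat: str  # 'reef' | 'muck'
    diel: str  # 'day' | 'night'
    hours: float  # searcher-hours of effort
    rate_per_hour: float  # true encounters per searcher-hour
    depth_range: tuple[float, float]  # meters, min <= max

    def __post_init__(self):
        if self.habitat not in ("reef", "muck"):
            raise ValueError("habitat must be 'reef' or 'muck'")
        if self.diel not in ("day", "night"):
            raise ValueError("diel must be 'day' or 'night'")
        if not np.isfinite(self.hours) or self.hours < 0:
            raise ValueError("hours must be finite and non-negative")
        if self.rate_per_hour < 0:
            raise ValueError("rate must be non-negative")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range min must not exceed max")


@dataclass(frozen=True)
class EffortSpec:
    """Full survey design: strata, searchers, calendar, and seed."""

    strata: tuple[StratumSpec, ...]
    seed: int
    n_searchers: int = 3
    start_date: dt.date = dt.date(2024, 11, 11)
    sample_interval_s: float = 10.0

    @classmethod
    def study_default(cls, seed: int = 0) -> "EffortSpec":
        """The survey's effort layout: 70.1 searcher-hours split over
        reef (57.4 h) and muck (12.7 h) sites by day (32.0 h) and night,
        with all encounters in the 6–12 m reef band after dark at the
        observed discovery rate (25 animals / 31.7 reef-night hours)."""
        return cls(
            strata=(
                StratumSpec("reef", "day", 25.7, 0.0, (2.0, 20.0)),
                StratumSpec("reef", "night", 31.7, 25.0 / 31.7, (6.0, 12.0)),
                StratumSpec("muck", "day", 6.3, 0.0, (4.0, 24.0)),
                StratumSpec("muck", "night", 6.4, 0.0, (4.0, 24.0)),
            ),
            seed=seed,
        )


# Daily searchable windows (local time) used when laying strata onto a
# calendar.  Day searching starts mid-morning; night searching starts
# after sunset (Anilao November sunset is ~17:40).
_DAY_WINDOW = (dt.time(8, 30), dt.time(16, 30))
_NIGHT_WINDOW = (dt.time(18, 30), dt.time(23, 59, 50))


def _window_seconds(window) -> float:
    t0, t1 = window
    return (
        dt.datetime.combine(dt.date.min, t1) - dt.datetime.combine(dt.date.min, t0)
    ).total_seconds()


def _bounded_walk(rng, n, lo, hi, step_sd=0.15):
    """Depth trace: reflected Gaussian random walk inside [lo, hi]."""
    if n == 0:
        return np.empty(0)
    z = np.empty(n)
    z[0] = (lo + hi) / 2.0
    steps = rng.normal(0.0, step_sd, size=n - 1)
    span = hi - lo
    for i in range(1, n):
        v = z[i - 1] + steps[i - 1]
        if span > 0:
            # reflect into range
            v = lo + abs((v - lo) % (2 * span))
            if v > hi:
                v = 2 * hi - v
        else:
            v = lo
        z[i] = v
    return z


def simulate_dive_logs(spec: EffortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate stratified searcher dive logs and Poisson encounters.

    Returns ``(logs, sightings)``:

    * ``logs`` — one row per 10-s depth sample: ``searcher_id``,
      ``timestamp`` (local, naive), ``depth_m``, ``habitat``, ``diel``.
    * ``sightings`` — one row per encounter: ``sighting_id``,
      ``timestamp``, ``depth_m``, ``habitat``.

    Per stratum the encounter count is Poisson(rate x realized hours);
    encounter times are uniform over that stratum's searched samples and
    encounter depths uniform in the stratum's depth range.  The same
    seed reproduces the output bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    dt_s = spec.sample_interval_s
    # cursor[(searcher, diel)] = (day_index, seconds already used today)
    cursor: dict[tuple[int, str], list[float]] = {}

    log_rows = []
    sight_rows = []
    sight_id = 0
    for stratum in spec.strata:
        total_samples = int(round(stratum.hours * 3600.0 / dt_s))
        # spread samples over searchers as evenly as integers allow
        base, extra = divmod(total_samples, spec.n_searchers)
        window = _DAY_WINDOW if stratum.diel == "day" else _NIGHT_WINDOW
        win_len = _window_seconds(window)
        stratum_rows = []
        for s in range(spec.n_searchers):
            n_left = base + (1 if s < extra else 0)
            key = (s, stratum.diel)
            day_idx, used = cursor.get(key, [0, 0.0])
            while n_left > 0:
                room = int((win_len - used) // dt_s)
                if room <= 0:
                    day_idx, used = day_idx + 1, 0.0
                    continue
                take = min(n_left, room)
                t0 = dt.datetime.combine(
                    spec.start_date + dt.timedelta(days=day_idx), window[0]
                ) + dt.timedelta(seconds=used)
                times = [t0 + dt.timedelta(seconds=i * dt_s) for i in range(take)]
                depths = _bounded_walk(rng, take, *stratum.depth_range)
                stratum_rows.extend(
                    {
                        "searcher_id": f"S{s + 1}",
                        "timestamp": t,
                        "depth_m": round(float(z), 3),
                        "habitat": stratum.habitat,
                        "diel": stratum.diel,
                    }
                    for t, z in zip(times, depths)
                )
                used += take * dt_s
                n_left -= take
            cursor[key] = [day_idx, used]
        log_rows.extend(stratum_rows)

        realized_hours = total_samples * dt_s / 3600.0
        n_enc = rng.poisson(stratum.rate_per_hour * realized_hours)
        if n_enc > 0 and stratum_rows:
            picks = rng.integers(0, len(stratum_rows), size=n_enc)
            lo, hi = stratum.depth_range
            enc_depths = rng.uniform(lo, hi, size=n_enc) if hi > lo else np.full(n_enc, lo)
            for p, z in zip(picks, enc_depths):
                sight_rows.append(
                    {
                        "sighting_id": f"C{sight_id:03d}",
                        "timestamp": stratum_rows[p]["timestamp"],
                        "depth_m": round(float(z), 2),
                        "habitat": stratum.habitat,
                    }
                )
                sight_id += 1

    logs = pd.DataFrame(
        log_rows, columns=["searcher_id", "timestamp", "depth_m", "habitat", "diel"]
    )
    sightings = pd.DataFrame(
        sight_rows, columns=["sighting_id", "timestamp", "depth_m", "habitat"]
    )
    logs = logs.sort_values(["searcher_id", "timestamp"], kind="stable").reset_index(drop=True)
    sightings = sightings.sort_values("timestamp", kind="stable").reset_index(drop=True)
    sightings["sighting_id"] = [f"C{i:03d}" for i in range(len(sightings))]
    return logs, sightings


# ---------------------------------------------------------------------------
# Laser-dot scenes
# ---------------------------------------------------------------------------

def render_laser_scene(
    mm_per_px: float,
    dot_separation_mm: float = 100.0,
    image_shape: tuple[int, int] = (600, 800),
    background: np.ndarray | None = None,
    dot_intensity: float = 1.0,
    dot_sigma_px: float = 2.0,
    noise_sd: float = 0.0,
    center: tuple[float, float] | None = None,
    angle_deg: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render a texture scene with two parallel-beam laser dots.

    The dots are Gaussian, green-dominant blobs whose centroid distance
    in pixels equals ``dot_separation_mm / mm_per_px`` (sub-pixel
    placement).  ``center`` and ``angle_deg`` position the pair; a
    ``ValueError`` is raised if either dot would fall outside the frame.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    if dot_separation_mm <= 0:
        raise ValueError("dot separation must be positive")
    rng = np.random.default_rng(rng)
    h, w = image_shape
    if background is None:
        # smooth low-contrast speckle standing in for sand/coral texture
        img = 0.12 + 0.08 * gaussian_filter(rng.standard_normal((h, w)), 3.0)
        img = np.clip(img, 0.0, 0.4)[..., None] * np.array([1.0, 0.95, 0.85])
    else:
        img = np.array(background, dtype=float, copy=True)
        if img.ndim == 2:
            img = img[..., None].repeat(3, axis=-1)
        h, w = img.shape[:2]

    sep_px = dot_separation_mm / mm_per_px
    cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    th = np.deg2rad(angle_deg)
    half = sep_px / 2.0
    dots = [
        (cy - half * np.sin(th), cx - half * np.cos(th)),
        (cy + half * np.sin(th), cx + half * np.cos(th)),
    ]
    margin = 3.0 * dot_sigma_px
    for (ry, rx) in dots:
        if not (margin <= ry <= h - 1 - margin and margin <= rx <= w - 1 - margin):
            raise ValueError("laser dots do not fit inside the image frame")

    yy, xx = np.mgrid[0:h, 0:w]
    blob = np.zeros((h, w))
    for (ry, rx) in dots:
        blob += np.exp(-((yy - ry) ** 2 + (xx - rx) ** 2) / (2 * dot_sigma_px**2))
    # green lasers: strong G, weak R/B bleed
    img = img + dot_intensity * blob[..., None] * np.array([0.25, 1.0, 0.25])
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)
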