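"""Configuration, stage plumbing, and the end-to-end reproducible run.

Each stage reads/writes plain formats (CSV tables with JSON sidecars,
16-bit linear TIFF rasters, JSON configs) so downstream use is
language-agnostic.  A run manifest records the seed, package version,
and SHA-256 of every file written; identical config + seed reproduces
identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import colorcard, depthsim, gamut, scalebar, survey, synth

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("cuttlefield")

STAGES = ("synth", "cardfit", "depthsim", "gamut", "survey", "scalebar")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a structured payload."""

    def __init__(self, stage: str, message: str, **details):
        self.stage = stage
        self.details = {"stage": stage, "error": message, **details}
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    Attributes cover the synthetic study conditions (optics, depths,
    effort strata), analysis options (interpolation mode, test
    alternative, renormalization), the diel boundary table, the seed,
    and the output directory.  Timestamps are local and naive; the
    timezone is declared, not applied.
    """

    outdir: str = "cuttlefield_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    timezone_label: str = "Asia/Manila"
    # water optics / card
    k: tuple[float, float, float] = synth.DEFAULT_ATTENUATION_PER_M
    noise_sd: float = 0.0
    depths: tuple[float, ...] = synth.SURVEY_DEPTHS_M
    # analysis options
    interpolation_mode: str = "exponential"
    alternative: str = "deficit"
    renormalize: bool = False
    simulation_depth_m: float = 10.0
    # survey
    sun_table: dict = field(default_factory=lambda: {"sunrise": "05:45", "sunset": "17:41"})
    # scale calibration
    mm_per_px_true: float = 0.2
    laser_separation_mm: float = scalebar.DEFAULT_SEPARATION_MM
    scalebar_mm: float = scalebar.DEFAULT_BAR_LENGTH_MM

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("k", "depths", "stages"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_image(path: Path, image: np.ndarray) -> None:
    """16-bit TIFF in the linear-intensity convention, with a JSON sidecar."""
    iio.imwrite(path, (np.clip(image, 0, 1) * 65535 + 0.5).astype(np.uint16))
    sidecar = {"encoding": "linear", "bitdepth": 16, "max_value": 65535}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _read_image(path: Path) -> np.ndarray:
    return iio.imread(path).astype(float) / 65535.0


def _write_csv(df: pd.DataFrame, path: Path, schema: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))


def stage_synth(cfg: PipelineConfig, out: Path) -> dict:
    optics = synth.WaterOpticsParams(k=cfg.k, noise_sd=cfg.noise_sd)
    layout = synth.CardLayout.default()
    rng = np.random.default_rng(cfg.seed)
    series = synth.render_card_series(optics, layout, cfg.depths, rng=rng)
    _write_csv(
        series.to_frame(),
        out / "card_series.csv",
        {"columns": ["depth_m", "panel_id", "R", "G", "B", "neutral"],
         "units": {"depth_m": "m", "RGB": "linear [0,1]"}},
    )
    spec = synth.EffortSpec.study_default(seed=cfg.seed)
    logs, sightings = synth.simulate_dive_logs(spec)
    logs_out = logs.assign(timestamp=logs["timestamp"].map(lambda t: t.isoformat()))
    s_out = sightings.assign(timestamp=sightings["timestamp"].map(lambda t: t.isoformat()))
    _write_csv(logs_out, out / "dive_logs.csv",
               {"columns": list(logs_out.columns), "timestamp": "ISO-8601 local",
                "timezone_label": cfg.timezone_label})
    _write_csv(s_out, out / "sightings.csv",
               {"columns": list(s_out.columns), "timestamp": "ISO-8601 local"})
    scene = synth.render_laser_scene(
        cfg.mm_per_px_true, cfg.laser_separation_mm, noise_sd=0.01,
        rng=np.random.default_rng(cfg.seed + 1),
    )
    _write_image(out / "laser_scene.tiff", scene)
    flash = synth.render_card_image(optics, layout, depth=cfg.simulation_depth_m, flash=True)
    ambient = synth.render_card_image(optics, layout, depth=cfg.simulation_depth_m, flash=False)
    _write_image(out / "flash_card.tiff", flash)
    _write_image(out / "ambient_card.tiff", ambient)
    return {"n_log_samples": len(logs), "n_sightings": len(sightings)}


def stage_cardfit(cfg: PipelineConfig, out: Path) -> dict:
    series = colorcard.ColorCardSeries.from_frame(pd.read_csv(out / "card_series.csv"))
    model = colorcard.fit_attenuation(series, interpolation_mode=cfg.interpolation_mode)
    payload = {
        "k_per_m": [None if not ok else float(v) for v, ok in zip(model.k, model.channel_ok)],
        "rmse_log": [float(v) for v in model.rmse_log],
        "n_excluded": [int(v) for v in model.n_excluded],
        "interpolation_mode": model.interpolation_mode,
        "negative_k": model.negative_k,
        "fit_panel_ids": list(model.panel_ids),
    }
    (out / "attenuation.json").write_text(json.dumps(payload, indent=2))
    return payload


def _load_model(cfg: PipelineConfig, out: Path) -> colorcard.AttenuationModel:
    series = colorcard.ColorCardSeries.from_frame(pd.read_csv(out / "card_series.csv"))
    return colorcard.fit_attenuation(series, interpolation_mode=cfg.interpolation_mode)


def stage_depthsim(cfg: PipelineConfig, out: Path) -> dict:
    model = _load_model(cfg, out)
    flash = depthsim.DepthTaggedImage(
        _read_image(out / "flash_card.tiff"), cfg.simulation_depth_m, "flash"
    )
    sim = depthsim.simulate_at_depth(flash, model, renormalize=cfg.renormalize)
    _write_image(out / "simulated_ambient.tiff", sim.pixels)
    truth = _read_image(out / "ambient_card.tiff")
    metrics = depthsim.compare_simulation(sim.pixels, truth)
    payload = {
        "depth_m": cfg.simulation_depth_m,
        "renormalize": cfg.renormalize,
        "mae": [float(v) for v in metrics["mae"]],
        "rmse": [float(v) for v in metrics["rmse"]],
        "hue_abs_error_deg": float(metrics["hue_abs_error_deg"]),
    }
    (out / "depthsim_metrics.json").write_text(json.dumps(payload, indent=2))
    return payload


def stage_gamut(cfg: PipelineConfig, out: Path) -> dict:
    series = colorcard.ColorCardSeries.from_frame(pd.read_csv(out / "card_series.csv"))
    sightings = None
    spath = out / "sightings.csv"
    if spath.exists():
        sightings = pd.read_csv(spath)
    profile = gamut.depth_gamut_profile(series, sightings)
    _write_csv(profile, out / "gamut_profile.csv",
               {"columns": list(profile.columns),
                "units": {"depth_m": "m", "hue": "deg", "chroma": "a.u.",
                          "area_ab": "chroma^2"}})
    return {"n_depths": len(profile), "surface_area": float(profile["area_ab"].iloc[0])}


def stage_survey(cfg: PipelineConfig, out: Path) -> dict:
    if not cfg.sun_table:
        raise PipelineError("survey", "missing required field: sun_table",
                            field="sun_table")
    sun = survey.SunTable.from_dict(cfg.sun_table)
    logs = pd.read_csv(out / "dive_logs.csv")
    sightings = pd.read_csv(out / "sightings.csv")
    table = survey.aggregate_effort(logs, sun)
    cells = table.cells.reset_index().rename(columns={0: "hours"})
    cells.columns = ["habitat", "diel", "hours"]
    _write_csv(cells, out / "effort_cells.csv", {"columns": list(cells.columns)})
    th = table.time_hist.rename_axis("time_bin").reset_index(name="hours")
    th["time_bin"] = th["time_bin"].map(lambda t: t.isoformat())
    _write_csv(th, out / "effort_time_hist.csv", {"bin": "15 min, left-closed"})
    dh = table.depth_hist.copy()
    dh.columns = ["_".join(c) for c in dh.columns]
    dh = dh.rename_axis("depth_bin_m").reset_index()
    _write_csv(dh, out / "effort_depth_hist.csv", {"bin": "1 m, left-closed"})

    s_diel = survey.diel_labels(pd.to_datetime(sightings["timestamp"]), sun)
    n_night_reef = int(((sightings["habitat"] == "reef") & (s_diel == "night")).sum())
    n = len(sightings)
    h_day, h_night = table.hours(diel="day"), table.hours(diel="night")
    h_reef, h_muck = table.hours(habitat="reef"), table.hours(habitat="muck")
    stats_payload = {
        "n_sightings": n,
        "n_night_reef": n_night_reef,
        "effort_hours": {"day": h_day, "night": h_night, "reef": h_reef,
                         "muck": h_muck, "total": table.total_hours},
        "expected_day": survey.expected_count(n, h_night, h_day) if h_night > 0 else None,
        "expected_muck": survey.expected_count(n, h_reef, h_muck) if h_reef > 0 else None,
        "p_day": survey.exact_poisson_rate_test(
            0, h_day, n, h_night, alternative=cfg.alternative) if h_night > 0 else None,
        "p_muck": survey.exact_poisson_rate_test(
            0, h_muck, n, h_reef, alternative=cfg.alternative) if h_reef > 0 else None,
        "alternative": cfg.alternative,
    }
    (out / "survey_stats.json").write_text(json.dumps(stats_payload, indent=2))
    return stats_payload


def stage_scalebar(cfg: PipelineConfig, out: Path) -> dict:
    image = _read_image(out / "laser_scene.tiff")
    calib = scalebar.LaserCalibration.from_image(image, cfg.laser_separation_mm)
    scale = scalebar.mm_per_pixel(calib)
    length_px, annotation = scalebar.scalebar_pixels(scale, cfg.scalebar_mm)
    payload = {
        "centroids_rc": [list(calib.centroid_1), list(calib.centroid_2)],
        "separation_mm": calib.separation_mm,
        "mm_per_px": scale,
        "scalebar": annotation,
    }
    (out / "laser_calibration.json").write_text(json.dumps(payload, indent=2))
    return {"mm_per_px": scale, "scalebar_px": length_px}


_STAGE_FUNCS = {
    "synth": stage_synth,
    "cardfit": stage_cardfit,
    "depthsim": stage_depthsim,
    "gamut": stage_gamut,
    "survey": stage_survey,
    "scalebar": stage_scalebar,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages in order and write a run manifest.

    Returns the manifest dict.  A stage failure raises
    :class:`PipelineError` after writing a structured error log.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for stage in cfg.stages:
        if stage not in _STAGE_FUNCS:
            raise PipelineError(stage, "unknown stage")
        log.info("running stage %s", stage)
        try:
            summaries[stage] = _STAGE_FUNCS[stage](cfg, out)
        except PipelineError as err:
            (out / "error.json").write_text(json.dumps(err.details, indent=2))
            raise
        except Exception as err:  # noqa: BLE001 - structured re-raise
            perr = PipelineError(stage, str(err))
            (out / "error.json").write_text(json.dumps(perr.details, indent=2))
            raise perr from err

    from . import __version__

    files = sorted(
        p.name for p in out.iterdir()
        if p.is_file() and p.name not in ("manifest.json", "error.json")
    )
    manifest = {
        "seed": cfg.seed,
        "version": __version__,
        "numpy": np.__version__,
        "stages": list(cfg.stages),
        "config": dataclasses.asdict(cfg),
        "outputs": {name: _sha256(out / name) for name in files},
        "summaries": summaries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
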