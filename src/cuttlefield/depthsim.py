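"""Ambient-light simulation of flash photographs at depth.

Nocturnal subjects can only be photographed under artificial light,
which reintroduces the full spectrum.  To approximate how a subject
actually appeared in ambient downwelling light, each channel of a
linear flash image is multiplied by the fitted water-column scale
``exp(-k_c z)`` for the photograph's depth — long-wavelength content is
removed in accordance with the color-card measurements.  An optional
renormalization restores the original peak brightness so that only the
hue shift, not the dimming, is shown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorcard import AttenuationModel, predict_channel_scale
from .gamut import linear_rgb_to_lab

__all__ = ["DepthTaggedImage", "simulate_at_depth", "compare_simulation"]

#: Pixels whose maximum channel is below this are excluded from the
#: chromaticity (hue-angle) comparison; hue is meaningless in the dark.
BRIGHTNESS_FLOOR = 0.02


@dataclass(frozen=True)
class DepthTaggedImage:
    """A linear-RGB raster with its capture depth and illumination mode."""

    pixels: np.ndarray  # (H, W, 3) linear RGB in [0, 1]
    depth: float  # meters
    illumination: str  # 'flash' | 'ambient'

    def __post_init__(self):
        pixels = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", pixels)
        if pixels.ndim != 3 or pixels.shape[-1] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.illumination not in ("flash", "ambient"):
            raise ValueError("illumination must be 'flash' or 'ambient'")
        if np.any(pixels < -1e-9) or np.any(pixels > 1 + 1e-9):
            raise ValueError("pixel values must lie in [0, 1]")


def simulate_at_depth(
    image: DepthTaggedImage,
    model: AttenuationModel,
    depth: float | None = None,
    renormalize: bool = False,
) -> DepthTaggedImage:
    """Simulate the ambient-light appearance of a flash image at depth.

    Each channel is multiplied by ``predict_channel_scale(model, depth)``.
    With ``renormalize=True`` a single global factor restores the
    output's maximum channel value to the input's maximum (the hue shift
    is preserved; overall exposure is not dimmed).  Output is clipped to
    [0, 1].
    """
    if image.illumination != "flash":
        raise ValueError("simulate_at_depth expects a flash-lit input image")
    z = image.depth if depth is None else depth
    if z < 0:
        raise ValueError("depth must be non-negative")
    scale = predict_channel_scale(model, z)
    out = image.pixels * scale
    if renormalize:
        peak_in = float(image.pixels.max())
        peak_out = float(out.max())
        if peak_out > 0:
            out = out * (peak_in / peak_out)
    return DepthTaggedImage(np.clip(out, 0.0, 1.0), z, "ambient")


def _hue_angles_deg(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    lab = linear_rgb_to_lab(pixels[mask])
    return np.rad2deg(np.arctan2(lab[:, 2], lab[:, 1])) % 360.0


def compare_simulation(sim, truth, brightness_floor: float = BRIGHTNESS_FLOOR) -> dict:
    """Quantitative error summary between a simulation and ground truth.

    Returns per-channel MAE and RMSE plus the mean absolute circular
    hue-angle difference (degrees, CIELAB) over pixels whose maximum
    channel exceeds ``brightness_floor`` in both images.  Inputs may be
    :class:`DepthTaggedImage` or bare arrays; shapes must match.
    """
    a = sim.pixels if isinstance(sim, DepthTaggedImage) else np.asarray(sim, dtype=float)
    b = truth.pixels if isinstance(truth, DepthTaggedImage) else np.asarray(truth, dtype=float)
    if a.shape != b.shape:
        raise ValueError("simulation and truth must have identical shapes")
    diff = a - b
    mae = np.abs(diff).reshape(-1, 3).mean(axis=0)
    rmse = np.sqrt((diff**2).reshape(-1, 3).mean(axis=0))
    mask = (a.max(axis=-1) >= brightness_floor) & (b.max(axis=-1) >= brightness_floor)
    if mask.any():
        ha = _hue_angles_deg(a, mask)
        hb = _hue_angles_deg(b, mask)
        d = np.abs(ha - hb)
        hue_err = float(np.minimum(d, 360.0 - d).mean())
    else:
        hue_err = np.nan
    return {
        "mae": mae,
        "rmse": rmse,
        "hue_abs_error_deg": hue_err,
        "n_hue_pixels": int(mask.sum()),
    }
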