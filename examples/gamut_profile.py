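"""Per-depth hue-chroma gamut polygons with sighting overlay.

The convex hull of the chart's panel colors in the CIELAB (a, b) plane
shrinks with depth as water strips long wavelengths; overlaying the
animal sighting depths shows what color gamut existed where the animals
actually live.
"""

import pandas as pd

from cuttlefield import WaterOpticsParams, depth_gamut_profile, render_card_series

series = render_card_series(WaterOpticsParams(k=(0.5, 0.07, 0.04)))
sightings = pd.DataFrame({"depth_m": [6.4, 7.1, 8.0, 9.5, 11.2, 11.9]})

profile = depth_gamut_profile(series, sightings)
cols = ["depth_m", "chroma_max", "area_ab", "n_sightings"]
print(profile[cols].round(2).to_string(index=False))
# area_ab is the gamut polygon area (squared chroma units): maximal at
# the surface and collapsing toward the blue/green axis by ~26 m.
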