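# Methods

## Water-column optics model

Downwelling sunlight in water loses intensity approximately exponentially
with depth, with a wavelength-dependent diffuse attenuation coefficient.
The package collapses this to the three broadband camera channels: a
panel with surface reflectance `R_c` viewed at depth `z` under ambient
light has linear intensity

```
I_c(z) = R_c · E_c(0) · exp(−k_c · z),   c ∈ {R, G, B}
```

where `E_c(0)` is the relative surface illuminant (default neutral,
(1, 1, 1)) and `k_c` ≥ 0 the per-channel attenuation coefficient (1/m).
Flash images are treated as full-spectrum: the camera-to-subject water
path is short enough that the depth term is omitted. Spectral radiative
transfer, scattering, and backscatter are out of scope — the model's job
is to describe channel-level color loss measured from a chart, not
in-water light fields.

Default generator coefficients are `k = (0.5, 0.07, 0.04)` 1/m, a
clear-tropical-water regime in which red falls to ~3% of its surface
value by 7 m while green and blue persist to the deepest station. The
depth grid defaults to the 11 survey stations from 0 to 25.7 m,
including the near-duplicate pair 11.7/11.8 m, which the fit treats as
two independent points.

## Attenuation fitting

`fit_attenuation` runs ordinary least squares on `log I_c` against depth,
pooled over the selected panels with one intercept per panel (the fitted
log surface intensity) and a single shared slope per channel (`−k_c`),
computed by within-panel demeaning. Defaults and numerical choices:

- **Fit panels**: the neutral ramp, when the series identifies one.
  Neutral panels isolate the illuminant change from panel chromaticity;
  colored panels can be pooled in explicitly.
- **Dark floor** ε = 1/255 in linear units: intensities at or below one
  8-bit quantization step are excluded from the log fit and counted in
  `n_excluded`. Below the floor, log-intensity is sensor noise.
  Consequence: once a channel's true signal sinks under the floor,
  clipped noise exceedances flatten its apparent slope — with noise
  sd 0.005 the red coefficient is only measurable over stations where
  red is genuinely bright (≲ 11 m at the default optics). The recovery
  guarantees in the tests are therefore scoped to channels that stay
  above the floor at every station; `examples/attenuation_fit.py` shows
  the shallow-station refit that recovers red.
- **Unfit channels**: fewer than 3 usable distinct depths → `k_c = NaN`
  with `channel_ok[c] = False`, never a silent extrapolation.
- **Negative slopes** are allowed (a series can brighten with depth
  through measurement error) but set a `negative_k` warning flag.
- **Interpolation modes**: `exponential` (default; extrapolates between
  and beyond stations via `exp(−k_c z)`) or `piecewise-linear`
  (interpolates the measured per-channel intensity ratios relative to
  the shallowest station, clamped outside the measured range) for users
  who prefer not to impose a functional form.

## Ambient-light simulation

`simulate_at_depth` multiplies each channel of a linear flash image by
`exp(−k_c z)` and clips to [0, 1]. `renormalize` defaults to **false**:
the simulated image is dimmer and blue-shifted, with no exposure
compensation; setting it true rescales by one global factor so the output
peak matches the input peak (hue shift preserved, exposure restored).
`compare_simulation` reports per-channel MAE/RMSE plus the mean absolute
circular CIELAB hue-angle difference over pixels whose maximum channel
exceeds 0.02 in both images (hue is meaningless in the dark).

## Colorimetry and gamut polygons

Linear RGB is converted to CIEXYZ with the sRGB primary matrix and then
to CIELAB against the D65 white point (taken as the matrix image of
RGB (1,1,1) so neutrals land exactly on a = b = 0). Camera RGB from a
raw decode with white balance off is treated as this sRGB dialect; a
`srgb_to_linear` helper is provided for gamma-encoded 8-bit input. Hue
is `atan2(b, a)` mapped to [0, 360) and flagged undefined below chroma
1e-6.

Gamut polygons are convex hulls computed in Cartesian (a, b), not in
polar (hue, chroma), because convexity is ill-defined on a circular hue
axis; the polygon's polar rendering is available as
`GamutPolygon.hue_chroma_vertices`. Areas use the shoelace formula on
the ordered hull vertices; single-point and collinear sets return area 0
with a `degenerate` flag. Sightings are overlaid on the depth profile by
assigning each sighting depth to the measured station whose half-open
bin (bounded by midpoints between consecutive stations) contains it.

## Survey statistics

Conventions, stated once: night is the half-open interval
[sunset, next sunrise); depth bins are [i, i+1) m; time-of-day bins are
[t, t+15 min). The diel boundary comes from a configurable
sunrise/sunset table (default 05:45/17:41 local, November values for the
survey region) with per-date overrides; a missing date with no default
is an error, never a silent guess.

Each 10-s log sample contributes one sample interval of effort to its
(habitat, diel) cell and to both histograms, so cell sums equal total
logged time exactly; duplicate timestamps within a searcher are rejected
as overlapping logs. A per-searcher averaged depth profile is available
for the "average time per searcher at each depth" view.

`exact_poisson_rate_test(x1, T1, x2, T2)` conditions on `n = x1 + x2`:
under equal rates, `x1 ~ Binomial(n, T1/(T1+T2))`. Tails are summed from
explicit binomial point masses; the two-sided p-value uses the
minimum-likelihood rule (sum of all outcomes no more probable than the
observed one, with a 1e-7 relative tie tolerance). The default
alternative is the one-tailed *deficit* test — the survey question is
whether a stratum with zero encounters is genuinely under-occupied. With
zero observed, the deficit p-value reduces to `(T2/(T1+T2))^n`. The
test is exact-or-conservative under discreteness, which the simulated
type-I error (≤ 5%) reflects.

The recorded effort totals carry a one-decimal rounding inconsistency:
reef + muck = 57.4 + 12.7 = 70.1 h but day + night = 32.0 + 38.2 =
70.2 h. The day/night test uses the day/night totals and the muck test
the habitat totals; the generator's default strata (reef-day 25.7,
reef-night 31.7, muck-day 6.3, muck-night 6.4 h) reproduce the reef,
muck, and day margins exactly, leaving night at 38.1 h — the residual of
the inconsistency, not a modeling choice.

## Scale calibration

Laser dots are found by thresholding a weighted-channel map at a high
quantile (default 0.999) — the default weights (−0.5, 1, −0.5) pick out
green excess over the red/blue mean, matching green lasers on a roughly
neutral scene. Connected components of ≥ 3 px are candidates; the two
with the largest integrated above-threshold intensity are taken as the
dots (intensity mass separates compact laser blobs from broad
low-contrast texture maxima), and their intensity-weighted centroids are
sub-pixel. Quantile thresholding and excess weighting make the result
invariant to uniform background offsets. Fewer than two candidates
raises a structured error carrying the count, at which point the
reference-object fallback (a user-measured pixel span of known physical
length) applies. Perspective correction is not attempted: the
parallel-beam separation is distance-invariant only for surfaces normal
to the optical axis, a documented limitation. Scale-bar annotations are
sidecar metadata; source pixels are never edited.

## Synthetic-data generator

The generator defines the study conditions the tests run under:

- **Color card**: 24 panels — 18 hues at 20° spacing (HSV s = 0.85,
  v = 0.8) plus a 6-step bright neutral ramp (0.95 … 0.20), a typical
  waterproof dive-chart inventory; the true chart's panel reflectances
  are not published, so these are stated defaults, not claims about the
  physical chart. Panel colors get additive Gaussian noise at the
  series level; raster renders apply per-pixel noise and attenuate the
  neutral background by the same lighting rule as the panels.
- **Dive logs**: the default effort layout reproduces the survey's
  margins (70.1 h total; reef 57.4, muck 12.7, day 32.0) across 3
  searchers, laid onto a calendar with day searching from 08:30 and
  night searching from 18:30 (after sunset). Depth traces are reflected
  Gaussian random walks (step sd 0.15 m per 10 s) inside each stratum's
  depth band. Encounters per stratum are Poisson(rate × realized
  hours) with times uniform over searched samples and depths uniform in
  the stratum band; the only nonzero default rate is night-reef
  (25/31.7 h ≈ 0.79/h) over the 6–12 m band where the animals were
  found. All randomness flows from one integer seed; same seed, same
  bytes.
- **Laser scenes**: smoothed-speckle background, two green-dominant
  Gaussian dots (σ = 2 px) at sub-pixel positions exactly
  `separation/mm_per_px` apart, plus optional pixel noise.

What the generator does *not* emulate — raw camera response, scattering
and veiling light, inhomogeneous illuminants, searcher behavior
(ascent/descent profiles, surface intervals), or depth-dependent
encounter rates within a stratum. Passing tests therefore demonstrate
the correctness of the estimators and plumbing under the stated model,
not robustness to every property of real field imagery.

## Problem sizes

Simulations are sized for interactive runs: 10,000 replicates for test
calibration, 20 seeds/scenes for noisy recovery and laser sweeps, 2,000
replicates for generator moment checks; the full suite and the
acceptance script each complete in well under a minute of compute per
component.
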