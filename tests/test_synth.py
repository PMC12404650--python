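"""Synthetic-data generator: rendering rule, Poisson encounters, lasers."""

import numpy as np
import pandas as pd
import pytest

from cuttlefield import (
    SURVEY_DEPTHS_M,
    CardLayout,
    EffortSpec,
    StratumSpec,
    WaterOpticsParams,
    render_card_image,
    render_card_series,
    render_laser_scene,
    simulate_dive_logs,
)
from cuttlefield.synth import CardPanel, ambient_panel_colors


class TestWaterOptics:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": (-0.1, 0.1, 0.1)},
            {"surface_illuminant": (0.0, 1.0, 1.0)},
            {"surface_illuminant": (1.2, 1.0, 1.0)},
            {"noise_sd": -0.01},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WaterOpticsParams(**kwargs)


class TestCardLayout:
    def test_default_has_24_panels_with_neutral_ramp(self, layout):
        assert len(layout.panels) == 24
        assert len(layout.neutral_panel_ids) == 6

    def test_overlapping_regions_rejected(self):
        panels = (
            CardPanel("a", (0.5, 0.5, 0.5), (0, 0, 10, 10)),
            CardPanel("b", (0.2, 0.3, 0.4), (5, 5, 15, 15)),
        )
        with pytest.raises(ValueError, match="overlap"):
            CardLayout(panels)

    def test_requires_neutral_panel(self):
        panels = (
            CardPanel("a", (0.5, 0.2, 0.1), (0, 0, 10, 10)),
            CardPanel("b", (0.2, 0.3, 0.4), (0, 20, 10, 30)),
        )
        with pytest.raises(ValueError, match="neutral"):
            CardLayout(panels)


class TestRenderCardSeries:
    def test_surface_colors_equal_reflectances(self, layout):
        """exp(0) = 1: at z = 0 with unit illuminant and no noise the
        panel colors are exactly the surface reflectances."""
        optics = WaterOpticsParams(noise_sd=0.0)
        series = render_card_series(optics, layout, depths=[0.0])
        np.testing.assert_array_equal(series.colors[0], layout.reflectances)

    def test_closed_form_at_10m(self):
        """Neutral 0.9 panel at 10 m: channel values 0.9 e^{-kz}."""
        layout = CardLayout(
            (
                CardPanel("n", (0.9, 0.9, 0.9), (0, 0, 4, 4)),
                CardPanel("c", (0.5, 0.2, 0.1), (0, 8, 4, 12)),
            )
        )
        optics = WaterOpticsParams(k=(0.5, 0.07, 0.04), noise_sd=0.0)
        series = render_card_series(optics, layout, depths=[10.0])
        np.testing.assert_allclose(
            series.colors[0, 0], [0.00607, 0.4469, 0.6033], atol=5e-5
        )

    def test_default_depth_grid_is_the_11_station_series(self, optics):
        series = render_card_series(optics)
        assert len(series.depths) == 11
        assert series.depths[0] == 0.0 and series.depths[-1] == 25.7
        np.testing.assert_array_equal(series.depths, SURVEY_DEPTHS_M)

    def test_flash_ignores_depth(self, optics, layout):
        shallow = render_card_series(optics, layout, depths=[1.0], flash=True)
        deep = render_card_series(optics, layout, depths=[20.0], flash=True)
        np.testing.assert_array_equal(shallow.colors, deep.colors)

    def test_ambient_intensity_strictly_decreasing_in_depth(self, optics, layout):
        series = render_card_series(optics, layout, depths=np.linspace(0, 20, 9))
        bright = series.colors[:, :, :]  # all k > 0 here
        assert np.all(np.diff(bright, axis=0) < 0)

    @pytest.mark.parametrize("bad_depths", [[], [-1.0, 5.0]])
    def test_invalid_depths_rejected(self, optics, layout, bad_depths):
        with pytest.raises(ValueError):
            render_card_series(optics, layout, depths=bad_depths)

    def test_noise_is_seed_deterministic(self, layout):
        optics = WaterOpticsParams(noise_sd=0.01)
        a = render_card_series(optics, layout, rng=7)
        b = render_card_series(optics, layout, rng=7)
        np.testing.assert_array_equal(a.colors, b.colors)

    def test_card_image_panels_match_rendering_rule(self, optics, layout):
        img = render_card_image(optics, layout, depth=10.0)
        expected = ambient_panel_colors(optics, layout, 10.0)
        for panel, color in zip(layout.panels, expected):
            r0, c0, r1, c1 = panel.region
            np.testing.assert_allclose(img[r0:r1, c0:c1].mean(axis=(0, 1)), color)


class TestSimulateDiveLogs:
    def test_zero_rate_produces_zero_sightings(self):
        spec = EffortSpec(
            strata=(StratumSpec("reef", "night", 5.0, 0.0, (5.0, 10.0)),),
            seed=3,
        )
        _, sightings = simulate_dive_logs(spec)
        assert len(sightings) == 0

    def test_same_seed_is_bit_identical(self):
        spec = EffortSpec.study_default(seed=11)
        logs_a, s_a = simulate_dive_logs(spec)
        logs_b, s_b = simulate_dive_logs(spec)
        pd.testing.assert_frame_equal(logs_a, logs_b)
        pd.testing.assert_frame_equal(s_a, s_b)

    def test_poisson_mean_and_variance_of_encounter_counts(self):
        """Monte-Carlo encounter counts from the generator match the
        Poisson mean and variance (rate x exposure) within 4 standard
        errors over 2000 replicates."""
        hours, rate, reps = 0.1, 50.0, 2000
        mean_expected = rate * hours  # 5.0
        strata = (StratumSpec("reef", "night", hours, rate, (6.0, 12.0)),)
        counts = np.array([
            len(simulate_dive_logs(EffortSpec(strata, seed=s, n_searchers=1))[1])
            for s in range(reps)
        ])
        se_mean = np.sqrt(mean_expected / reps)
        assert abs(counts.mean() - mean_expected) < 4 * se_mean
        # Var of the sample variance of a Poisson: (mu + 2 mu^2)/reps
        se_var = np.sqrt((mean_expected + 2 * mean_expected**2) / reps)
        assert abs(counts.var(ddof=1) - mean_expected) < 4 * se_var

    def test_study_scale_count_matches_expected_rate(self):
        """At the survey's own night-reef rate the mean count over a few
        seeds sits near rate x exposure."""
        mean_expected = 25.0
        sub_counts = [
            len(simulate_dive_logs(EffortSpec.study_default(seed=s))[1])
            for s in range(20)
        ]
        assert abs(np.mean(sub_counts) - mean_expected) < 4 * np.sqrt(mean_expected / 20)

    def test_depths_and_labels_respect_stratum(self):
        spec = EffortSpec(
            strata=(StratumSpec("muck", "day", 2.0, 3.0, (4.0, 9.0)),),
            seed=2,
        )
        logs, sightings = simulate_dive_logs(spec)
        assert set(logs["habitat"]) == {"muck"}
        assert set(logs["diel"]) == {"day"}
        assert logs["depth_m"].between(4.0, 9.0).all()
        assert sightings["depth_m"].between(4.0, 9.0).all()

    def test_ten_second_sampling(self):
        spec = EffortSpec(
            strata=(StratumSpec("reef", "day", 0.5, 0.0, (5.0, 6.0)),),
            seed=0, n_searchers=1,
        )
        logs, _ = simulate_dive_logs(spec)
        deltas = logs["timestamp"].diff().dropna().dt.total_seconds()
        assert (deltas == 10.0).all()
        assert len(logs) == int(0.5 * 360)


class TestRenderLaserScene:
    def test_dot_separation_in_pixels(self):
        """0.2 mm/px and 100 mm separation puts the dots 500 px apart."""
        img = render_laser_scene(0.2, 100.0, image_shape=(300, 700), rng=0)
        # green-excess peak in each half of the frame marks one dot
        excess = img[..., 1] - (img[..., 0] + img[..., 2]) / 2
        _, x_left = np.unravel_index(np.argmax(excess[:, :350]), (300, 350))
        _, x_right = np.unravel_index(np.argmax(excess[:, 350:]), (300, 350))
        assert abs((x_right + 350) - x_left - 500) <= 1

    def test_default_separation_is_100mm(self):
        import inspect

        sig = inspect.signature(render_laser_scene)
        assert sig.parameters["dot_separation_mm"].default == 100.0

    def test_out_of_frame_dots_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            render_laser_scene(0.05, 100.0, image_shape=(200, 300), rng=0)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            render_laser_scene(-0.1)
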