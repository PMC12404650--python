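"""Effort aggregation, rate transfer, and the exact Poisson rate test."""

import datetime as dt
from math import comb

import numpy as np
import pandas as pd
import pytest

from cuttlefield import (
    EffortSpec,
    StratumSpec,
    SunTable,
    aggregate_effort,
    classify_diel,
    exact_poisson_rate_test,
    expected_count,
    simulate_dive_logs,
)

SUN = SunTable(sunrise=dt.time(5, 45), sunset=dt.time(17, 41))


class TestClassifyDiel:
    @pytest.mark.parametrize(
        "ts, expected",
        [
            ("2024-11-12 17:42:00", "night"),  # one minute after sunset
            ("2024-11-12 17:41:00", "night"),  # exactly sunset: half-open
            ("2024-11-12 12:00:00", "day"),  # noon
            ("2024-11-12 05:44:50", "night"),  # pre-dawn belongs to night
            ("2024-11-12 05:45:00", "day"),  # exactly sunrise: day
        ],
    )
    def test_boundaries(self, ts, expected):
        assert classify_diel(pd.Timestamp(ts), dt.time(17, 41), dt.time(5, 45)) == expected

    def test_missing_date_entry_errors(self):
        table = SunTable(sunrise=None, sunset=None, overrides={})
        with pytest.raises(KeyError):
            table.times_for(dt.date(2024, 11, 12))


def contiguous_log(habitat, start, hours, searcher="S1", depth=7.0):
    n = int(hours * 360)
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "searcher_id": searcher,
            "timestamp": [t0 + pd.Timedelta(seconds=10 * i) for i in range(n)],
            "depth_m": depth,
            "habitat": habitat,
        }
    )


class TestAggregateEffort:
    def test_one_hour_contiguous_reef_day(self):
        logs = contiguous_log("reef", "2024-11-12 10:00:00", 1.0)
        table = aggregate_effort(logs, SUN)
        assert table.hours("reef", "day") == pytest.approx(1.0)
        assert table.total_hours == pytest.approx(1.0)

    def test_generator_round_trip_recovers_cells(self):
        """Effort cells recovered from synthetic logs match the effort
        specification to within one 10-s sample interval."""
        spec = EffortSpec.study_default(seed=4)
        logs, _ = simulate_dive_logs(spec)
        table = aggregate_effort(logs, SUN)
        for stratum in spec.strata:
            got = table.hours(stratum.habitat, stratum.diel)
            assert abs(got - stratum.hours) <= 10.0 / 3600.0

    def test_conservation_of_effort(self):
        spec = EffortSpec.study_default(seed=9)
        logs, _ = simulate_dive_logs(spec)
        table = aggregate_effort(logs, SUN)
        assert table.conservation_gap_hours() < 1e-9
        assert table.time_hist.sum() == pytest.approx(table.total_hours)
        assert table.depth_hist.to_numpy().sum() == pytest.approx(table.total_hours)

    def test_splitting_a_log_changes_no_totals(self):
        logs = contiguous_log("muck", "2024-11-12 09:00:00", 2.0)
        whole = aggregate_effort(logs, SUN)
        part = aggregate_effort(
            pd.concat([logs.iloc[:300], logs.iloc[300:]]), SUN
        )
        pd.testing.assert_series_equal(whole.cells, part.cells)

    def test_duplicate_samples_rejected(self):
        logs = contiguous_log("reef", "2024-11-12 10:00:00", 0.1)
        dup = pd.concat([logs, logs.iloc[[5]]])
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_effort(dup, SUN)

    def test_histogram_bin_conventions(self):
        # 30 min of effort starting 10:00 -> bins 10:00 and 10:15 only
        logs = contiguous_log("reef", "2024-11-12 10:00:00", 0.5, depth=3.4)
        table = aggregate_effort(logs, SUN)
        assert set(table.time_hist.index) == {dt.time(10, 0), dt.time(10, 15)}
        # depth 3.4 m falls in the [3, 4) bin
        assert list(table.depth_hist.index) == [3]

    def test_average_searcher_depth_profile(self):
        a = contiguous_log("reef", "2024-11-12 10:00:00", 1.0, searcher="S1", depth=5.5)
        b = contiguous_log("reef", "2024-11-12 10:00:00", 0.5, searcher="S2", depth=5.2)
        table = aggregate_effort(pd.concat([a, b]), SUN)
        prof = table.average_searcher_depth_profile()
        assert prof[("reef", "day")].loc[5] == pytest.approx(0.75)


class TestExpectedCount:
    @pytest.mark.parametrize(
        "n, e_obs, e_target, printed",
        [
            (25, 38.2, 32.0, "20.9"),  # daytime expectation from night rate
            (25, 57.4, 12.7, "5.5"),  # muck expectation from reef rate
        ],
    )
    def test_printed_study_values(self, n, e_obs, e_target, printed):
        assert f"{expected_count(n, e_obs, e_target):.1f}" == printed

    def test_zero_observed_count(self):
        assert expected_count(0, 38.2, 32.0) == 0.0

    def test_zero_effort_rejected(self):
        with pytest.raises(ValueError):
            expected_count(25, 0.0, 32.0)


def binomial_tail_oracle(x1, n, p, alternative):
    """Independent enumeration of the conditional binomial tails."""
    pmf = [comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    if alternative == "deficit":
        return sum(pmf[: x1 + 1])
    if alternative == "excess":
        return sum(pmf[x1:])
    return sum(q for q in pmf if q <= pmf[x1] * (1 + 1e-7))


class TestExactPoissonRateTest:
    def test_daytime_deficit_p_value(self):
        """No animals in 32.0 day-hours against 25 in 38.2 night-hours:
        the deficit tail is (38.2/70.2)^25 ~ 2.47e-7."""
        p = exact_poisson_rate_test(0, 32.0, 25, 38.2, "deficit")
        assert p == pytest.approx((38.2 / 70.2) ** 25, rel=1e-12)
        assert p == pytest.approx(2.47e-7, rel=0.01)

    def test_muck_deficit_p_value(self):
        p = exact_poisson_rate_test(0, 12.7, 25, 57.4, "deficit")
        assert p == pytest.approx((57.4 / 70.1) ** 25, rel=1e-12)
        assert p == pytest.approx(6.8e-3, rel=0.01)

    def test_empty_survey_gives_p_one(self):
        for alt in ("deficit", "excess", "two-sided"):
            assert exact_poisson_rate_test(0, 1.0, 0, 1.0, alt) == 1.0

    def test_full_tail_is_one(self):
        assert exact_poisson_rate_test(25, 32.0, 0, 38.2, "deficit") == pytest.approx(1.0)
        assert exact_poisson_rate_test(0, 32.0, 25, 38.2, "excess") == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["deficit", "excess", "two-sided"])
    def test_matches_enumeration_oracle_all_n_to_60(self, alternative):
        """Exhaustive agreement with direct binomial enumeration for
        every split of every total count n <= 60."""
        T1, T2 = 32.0, 38.2
        p1 = T1 / (T1 + T2)
        for n in range(61):
            for x1 in range(n + 1):
                got = exact_poisson_rate_test(x1, T1, n - x1, T2, alternative)
                want = binomial_tail_oracle(x1, n, p1, alternative)
                assert got == pytest.approx(min(want, 1.0), rel=1e-9, abs=1e-300)

    @pytest.mark.parametrize("bad", [0.5, -1, 2.5])
    def test_non_integer_or_negative_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            exact_poisson_rate_test(bad, 1.0, 3, 1.0)

    def test_type_one_error_calibration(self):
        """Under equal true rates the deficit test at alpha = 0.05 is
        exact-or-conservative: rejection in at most 5.5% of replicates
        (discreteness makes it conservative)."""
        rng = np.random.default_rng(1234)
        T1, T2, lam, reps = 32.0, 38.2, 0.5, 2000
        x1 = rng.poisson(lam * T1, reps)
        x2 = rng.poisson(lam * T2, reps)
        rej = np.array([
            exact_poisson_rate_test(a, T1, b, T2, "deficit") <= 0.05
            for a, b in zip(x1, x2)
        ])
        assert rej.mean() <= 0.055
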