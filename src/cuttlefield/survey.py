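"""Effort-standardized encounter statistics for a stratified visual survey.

Dive-computer logs (depth every 10 s per searcher) are aggregated into
searcher-hours of effort per habitat (reef/muck) and diel period
(day/night), plus the time-of-day (15-min bins) and depth (1-m bins)
effort histograms.  Encounter counts are compared across strata under a
homogeneous-Poisson null: transferring the observed discovery rate to a
target stratum gives its expected count, and the exact Poisson rate
test conditions on the total count, under which the split between two
strata is Binomial with probability proportional to exposure.

Conventions (stated once, used everywhere): diel classification is
half-open, night = [sunset, next sunrise); depth bins are [i, i+1) m;
time bins are [t, t+15 min).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SunTable",
    "EffortTable",
    "classify_diel",
    "diel_labels",
    "aggregate_effort",
    "expected_count",
    "exact_poisson_rate_test",
]


@dataclass(frozen=True)
class SunTable:
    """Per-date sunrise/sunset lookup with optional constant defaults.

    ``overrides`` maps ``datetime.date`` to ``(sunrise, sunset)`` local
    times.  If no default times are given, a date absent from
    ``overrides`` raises ``KeyError`` (the diel split is meaningless
    without a sunset for that date).
    """

    sunrise: dt.time | None = dt.time(5, 45)
    sunset: dt.time | None = dt.time(17, 41)
    overrides: Mapping[dt.date, tuple[dt.time, dt.time]] = field(default_factory=dict)

    def times_for(self, date: dt.date) -> tuple[dt.time, dt.time]:
        if date in self.overrides:
            return self.overrides[date]
        if self.sunrise is None or self.sunset is None:
            raise KeyError(f"no sunrise/sunset entry for {date}")
        return (self.sunrise, self.sunset)

    @classmethod
    def from_dict(cls, d: dict) -> "SunTable":
        parse = dt.time.fromisoformat
        overrides = {
            dt.date.fromisoformat(k): (parse(v["sunrise"]), parse(v["sunset"]))
            for k, v in d.get("overrides", {}).items()
        }
        return cls(
            sunrise=parse(d["sunrise"]) if d.get("sunrise") else None,
            sunset=parse(d["sunset"]) if d.get("sunset") else None,
            overrides=overrides,
        )


def classify_diel(timestamp, sunset_time: dt.time, sunrise_time: dt.time) -> str:
    """Classify one local timestamp as 'day' or 'night'.

    Night is the half-open interval [sunset, next sunrise): a timestamp
    at exactly sunset is night; one at exactly sunrise is day.
    """
    t = pd.Timestamp(timestamp).time()
    if t >= sunset_time or t < sunrise_time:
        return "night"
    return "day"


def diel_labels(timestamps, sun_table: SunTable) -> pd.Series:
    """Vectorised diel classification using a per-date sun table."""
    ts = pd.to_datetime(pd.Series(timestamps))
    out = []
    for t in ts:
        sunrise, sunset = sun_table.times_for(t.date())
        out.append(classify_diel(t, sunset, sunrise))
    return pd.Series(out, index=ts.index, dtype="object")


_CELLS = pd.MultiIndex.from_product(
    [["reef", "muck"], ["day", "night"]], names=["habitat", "diel"]
)


@dataclass(frozen=True)
class EffortTable:
    """Stratified search effort plus its marginal histograms.

    ``cells`` is indexed by (habitat, diel) in hours; ``time_hist`` by
    15-min bin start (time of day); ``depth_hist`` by 1-m bin floor,
    with one column per (habitat, diel) cell.  ``depth_by_searcher``
    retains the per-searcher split for per-searcher averaging.
    """

    cells: pd.Series
    time_hist: pd.Series
    depth_hist: pd.DataFrame
    depth_by_searcher: pd.DataFrame
    sample_interval_s: float
    n_samples: int

    @property
    def total_hours(self) -> float:
        return float(self.cells.sum())

    def hours(self, habitat: str | None = None, diel: str | None = None) -> float:
        sel = self.cells
        if habitat is not None:
            sel = sel.xs(habitat, level="habitat", drop_level=False)
        if diel is not None:
            sel = sel.xs(diel, level="diel", drop_level=False)
        return float(sel.sum())

    def average_searcher_depth_profile(self) -> pd.DataFrame:
        """Mean hours per depth bin across searchers (per habitat/diel) —
        the 'average time spent by each searcher at each depth' view."""
        return self.depth_by_searcher.groupby(level=["habitat", "diel"]).mean().T

    def conservation_gap_hours(self) -> float:
        """|sum of cells - total logged time|; should be ~0."""
        logged = self.n_samples * self.sample_interval_s / 3600.0
        return abs(self.total_hours - logged)


def aggregate_effort(
    logs: pd.DataFrame,
    sun_table: SunTable,
    sample_interval_s: float = 10.0,
) -> EffortTable:
    """Aggregate dive logs into the stratified effort table.

    Each depth sample contributes one sample interval (default 10 s) of
    effort to its (habitat, diel) cell, its 15-min time-of-day bin, and
    its 1-m depth bin.  Diel is derived from the timestamp and the sun
    table.  Duplicate timestamps for one searcher indicate overlapping
    logs and raise ``ValueError``.
    """
    required = {"searcher_id", "timestamp", "depth_m", "habitat"}
    missing = required - set(logs.columns)
    if missing:
        raise ValueError(f"logs are missing columns: {sorted(missing)}")
    logs = logs.copy()
    logs["timestamp"] = pd.to_datetime(logs["timestamp"])
    if logs.duplicated(subset=["searcher_id", "timestamp"]).any():
        raise ValueError("overlapping duplicate samples for one searcher")
    logs = logs.sort_values(["searcher_id", "timestamp"], kind="stable")
    logs["diel"] = diel_labels(logs["timestamp"], sun_table).to_numpy()

    w = sample_interval_s / 3600.0
    cells = (
        logs.groupby(["habitat", "diel"]).size().reindex(_CELLS, fill_value=0) * w
    ).rename("hours")

    seconds = (
        logs["timestamp"].dt.hour * 3600
        + logs["timestamp"].dt.minute * 60
        + logs["timestamp"].dt.second
    )
    logs["time_bin"] = (seconds // 900 * 900).map(
        lambda s: dt.time(int(s) // 3600, (int(s) % 3600) // 60)
    )
    time_hist = (logs.groupby("time_bin").size() * w).rename("hours")

    logs["depth_bin"] = np.floor(logs["depth_m"]).astype(int)
    depth_hist = (
        logs.groupby(["depth_bin", "habitat", "diel"]).size().unstack(["habitat", "diel"], fill_value=0)
        * w
    ).sort_index()
    depth_by_searcher = (
        logs.groupby(["habitat", "diel", "searcher_id", "depth_bin"]).size() * w
    ).unstack("depth_bin", fill_value=0.0)

    return EffortTable(
        cells=cells,
        time_hist=time_hist,
        depth_hist=depth_hist,
        depth_by_searcher=depth_by_searcher,
        sample_interval_s=sample_interval_s,
        n_samples=len(logs),
    )


def expected_count(n_obs: float, effort_obs: float, effort_target: float) -> float:
    """Expected count in a target stratum under rate transfer.

    Under a homogeneous-Poisson null the discovery rate observed in one
    stratum (``n_obs`` encounters over ``effort_obs`` hours) predicts
    ``n_obs * effort_target / effort_obs`` encounters over
    ``effort_target`` hours.
    """
    if effort_obs <= 0:
        raise ValueError("effort_obs must be positive")
    if effort_target < 0 or n_obs < 0:
        raise ValueError("counts and efforts must be non-negative")
    return n_obs * effort_target / effort_obs


def _check_count(x) -> int:
    if isinstance(x, (bool, np.bool_)):
        raise ValueError("counts must be integers")
    xf = float(x)
    if not xf.is_integer() or xf < 0:
        raise ValueError("counts must be non-negative integers")
    return int(xf)


def exact_poisson_rate_test(
    x1, T1: float, x2, T2: float, alternative: str = "deficit"
) -> float:
    """Exact two-sample Poisson rate test conditioned on the total count.

    Under equal rates, given ``n = x1 + x2``, ``x1`` is
    Binomial(n, T1 / (T1 + T2)).  Tail probabilities are computed by
    explicit summation of binomial point masses (no normal
    approximation):

    * ``deficit``  — P(X <= x1): is stratum 1's count too small?
    * ``excess``   — P(X >= x1)
    * ``two-sided`` — minimum-likelihood method: the sum of all outcome
      probabilities not exceeding the observed outcome's probability.
    """
    x1 = _check_count(x1)
    x2 = _check_count(x2)
    if T1 <= 0 or T2 <= 0:
        raise ValueError("exposures must be positive")
    if alternative not in ("deficit", "excess", "two-sided"):
        raise ValueError("alternative must be 'deficit', 'excess' or 'two-sided'")
    n = x1 + x2
    if n == 0:
        return 1.0
    p1 = T1 / (T1 + T2)
    pmf = stats.binom.pmf(np.arange(n + 1), n, p1)
    if alternative == "deficit":
        p = pmf[: x1 + 1].sum()
    elif alternative == "excess":
        p = pmf[x1:].sum()
    else:
        p = pmf[pmf <= pmf[x1] * (1 + 1e-7)].sum()
    return float(min(p, 1.0))
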