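"""Frost events: lethal cold spells for overwintering larvae.

Larvae survive at most three days at 0 degC or lower, so a frost event is a
maximal run of >= 3 consecutive days with daily mean temperature <= 0 degC.
Each maximal run counts once however long it is (one cohort dies once). The
average number of events per year over a daily temperature series, mapped
over a gridded daily dataset, delineates where larval overwintering is
impossible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["FrostEventSummary", "count_frost_events", "events_by_start_year", "frost_map"]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class FrostEventSummary:
    """Frost-event count over an observation span."""

    n_events: int
    n_years: float
    events_per_year: float
    event_starts: tuple  # pandas Timestamps of each run's first day

    def __post_init__(self) -> None:
        if self.n_events < 0 or self.n_years <= 0:
            raise ValueError("need n_events >= 0 and a positive span")


def _run_starts(cold: np.ndarray, min_run_days: int) -> np.ndarray:
    """Start indices of maximal True-runs of length >= min_run_days."""
    if cold.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate(([False], cold, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    keep = (ends - starts) >= min_run_days
    return starts[keep]


def _as_series(series) -> pd.Series:
    if isinstance(series, pd.DataFrame):
        series = pd.Series(
            series["temperature_C"].to_numpy(),
            index=pd.to_datetime(series["date"]),
            name="temperature_C",
        )
    if not isinstance(series, pd.Series):
        raise TypeError("series must be a pandas Series or a (date, temperature_C) frame")
    if series.empty:
        raise ValueError("empty temperature series")
    idx = pd.DatetimeIndex(series.index)
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise ValueError("dates must be strictly increasing")
    return pd.Series(series.to_numpy(dtype=float), index=idx, name="temperature_C")


def count_frost_events(
    series,
    threshold_C: float = 0.0,
    min_run_days: int = 3,
) -> FrostEventSummary:
    """Count maximal runs of >= min_run_days consecutive days at <= threshold.

    Accepts a date-indexed Series or a (date, temperature_C) DataFrame.
    Calendar gaps split the series: a candidate run may not bridge a gap.
    Runs are non-overlapping by maximality; a run spanning a year boundary
    belongs to the year of its first day. The per-year rate divides by the
    exact span in days / 365.25 (leap days, when present, are kept).
    """
    s = _as_series(series)
    day_gaps = np.diff(s.index.to_numpy()) / np.timedelta64(1, "D")
    seg_breaks = np.flatnonzero(day_gaps != 1.0) + 1
    starts_all = []
    for seg in np.split(np.arange(len(s)), seg_breaks):
        cold = s.to_numpy()[seg] <= threshold_C
        for st in _run_starts(cold, min_run_days):
            starts_all.append(s.index[seg[0] + st])
    n_days = (s.index[-1] - s.index[0]) / pd.Timedelta(days=1) + 1
    n_years = float(n_days) / DAYS_PER_YEAR
    n_events = len(starts_all)
    return FrostEventSummary(
        n_events=n_events,
        n_years=n_years,
        events_per_year=n_events / n_years,
        event_starts=tuple(starts_all),
    )


def events_by_start_year(summary: FrostEventSummary) -> pd.Series:
    """Event counts per calendar year, each run attributed to its start year."""
    years = pd.Series([ts.year for ts in summary.event_starts], dtype=int)
    return years.value_counts().sort_index()


def frost_map(
    grid: xr.DataArray,
    threshold_C: float = 0.0,
    min_run_days: int = 3,
) -> xr.DataArray:
    """Average frost events per year for every cell of a daily (time, lat, lon) grid.

    Cells with any missing day are treated as no-data (NaN). The time axis
    must be gap-free; gaps in gridded daily data should be handled by
    splitting the grid before mapping.
    """
    if "time" not in grid.dims:
        raise ValueError("grid must have a 'time' dimension")
    g = grid.transpose("time", ...)
    times = pd.DatetimeIndex(g["time"].to_numpy())
    if len(times) < 2 or not ((times[1:] - times[:-1]) == pd.Timedelta(days=1)).all():
        raise ValueError("gridded daily data must be gap-free along time")
    vals = g.to_numpy()
    nt = vals.shape[0]
    flat = vals.reshape(nt, -1)
    cold = flat <= threshold_C  # NaN compares False; NaN cells masked below
    # a qualifying run's start: min_run_days cold days not preceded by a cold day
    window = np.ones(flat.shape[1:], dtype=bool)
    counts = np.zeros(flat.shape[1:], dtype=float)
    for offset in range(nt - min_run_days + 1):
        window = cold[offset]
        for j in range(1, min_run_days):
            window = window & cold[offset + j]
        if offset > 0:
            window = window & ~cold[offset - 1]
        counts += window
    n_years = nt / DAYS_PER_YEAR
    rate = counts / n_years
    rate[np.isnan(flat).any(axis=0)] = np.nan
    out_dims = [d for d in g.dims if d != "time"]
    return xr.DataArray(
        rate.reshape([g.sizes[d] for d in out_dims]),
        dims=out_dims,
        coords={d: g.coords[d] for d in out_dims if d in g.coords},
        name="frost_events_per_year",
        attrs={"threshold_C": threshold_C, "min_run_days": min_run_days},
    )
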