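"""Potential generations per year from a generation-time model and climate.

The generation time at temperature T (degC) is modelled as

    G(T) = A exp(-k T) + c   [days],

the exponential age-at-emergence fit shifted by a 14-day pre-oviposition
period (copulation, blood meal, egg maturation). Default coefficients
A = 290.75 d, k = 0.17 1/degC, c = 22.32 d. Annual voltinism is accumulated
over monthly blocks: sum over months of days_in_month / G(T_month), on a
365-day calendar. Applied cell-wise to 12-band monthly mean temperature
rasters this yields a map of potential generations per year; climate
scenarios given as monthly tmin/tmax pairs are reduced to their midpoint
first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GenerationTimeModel",
    "MONTH_DAYS",
    "generation_time",
    "annual_generations",
    "voltinism_map",
    "scenario_temperatures",
    "extract_points",
    "read_raster",
    "write_raster",
]

MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)  # 365-day year


@dataclass(frozen=True)
class GenerationTimeModel:
    """G(T) = A exp(-k T) + c, days; strictly decreasing in T for k > 0.

    shift_days records the pre-oviposition period already folded into c
    relative to the raw age-at-emergence fit.
    """

    A: float = 290.75
    k: float = 0.17
    c: float = 22.32
    shift_days: float = 14.0

    def __post_init__(self) -> None:
        if self.A < 0 or self.k <= 0 or self.c <= 0:
            raise ValueError("generation-time model needs A >= 0, k > 0, c > 0")

    @classmethod
    def from_emergence_fit(cls, fit, shift_days: float = 14.0) -> "GenerationTimeModel":
        """Build G(T) from an age-at-emergence fit plus the oviposition shift."""
        return cls(A=fit.A, k=fit.k, c=fit.c + shift_days, shift_days=shift_days)

    def __call__(self, t):
        return generation_time(t, self)


def generation_time(t, model: GenerationTimeModel | None = None):
    """Generation time in days at temperature t (degC)."""
    model = model or GenerationTimeModel()
    t = np.asarray(t, dtype=float)
    g = model.A * np.exp(-model.k * t) + model.c
    return float(g) if g.ndim == 0 else g


def annual_generations(
    monthly_temps,
    model: GenerationTimeModel | None = None,
    month_days=MONTH_DAYS,
    t_min_cutoff: float | None = None,
):
    """Potential generations per year from 12 monthly mean temperatures.

    Sum over months of days_in_month / G(T_month). Any missing (NaN) month
    makes the result NaN. t_min_cutoff, if given, zeroes the contribution of
    months at or below the developmental minimum (off by default: the
    generation-time curve is applied as printed, cold months contributing
    negligibly but non-zero).
    """
    model = model or GenerationTimeModel()
    temps = np.asarray(monthly_temps, dtype=float)
    if temps.shape[0] != 12:
        raise ValueError("need exactly 12 monthly temperatures")
    days = np.asarray(month_days, dtype=float)
    if days.shape != (12,):
        raise ValueError("month_days must have 12 entries")
    shape = [12] + [1] * (temps.ndim - 1)
    contrib = days.reshape(shape) / generation_time(temps, model)
    if t_min_cutoff is not None:
        contrib = np.where(temps > t_min_cutoff, contrib, 0.0)
        contrib = np.where(np.isnan(temps), np.nan, contrib)
    total = contrib.sum(axis=0)  # NaN months propagate
    return float(total) if np.ndim(total) == 0 else total


def voltinism_map(
    raster: xr.DataArray,
    model: GenerationTimeModel | None = None,
    t_min_cutoff: float | None = None,
) -> xr.DataArray:
    """Per-cell potential generations per year from a 12-band monthly raster.

    Expects dims (month, lat, lon) with month = 1..12. No-data cells (NaN in
    any band) propagate to NaN. The result carries the unmasked-region
    summary (mean, min, max) in attrs.
    """
    if "month" not in raster.dims or raster.sizes["month"] != 12:
        raise ValueError("raster must have a 'month' dimension of length 12")
    data = raster.transpose("month", ...).to_numpy()
    values = annual_generations(data, model, t_min_cutoff=t_min_cutoff)
    out = xr.DataArray(
        values,
        dims=[d for d in raster.transpose("month", ...).dims if d != "month"],
        coords={d: raster.coords[d] for d in raster.dims if d != "month"},
        name="generations_per_year",
    )
    finite = values[np.isfinite(values)]
    if finite.size:
        out.attrs.update(
            summary_mean=float(finite.mean()),
            summary_min=float(finite.min()),
            summary_max=float(finite.max()),
        )
    return out


def scenario_temperatures(tmin_raster: xr.DataArray, tmax_raster: xr.DataArray) -> xr.DataArray:
    """Monthly mean temperature as the midpoint of scenario tmin and tmax."""
    if tmin_raster.sizes != tmax_raster.sizes:
        raise ValueError("tmin and tmax rasters must share their grid")
    mid = (tmin_raster + tmax_raster) / 2.0
    mid.name = "temperature_C"
    return mid


def extract_points(voltinism: xr.DataArray, points: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell voltinism at occurrence points (columns id, lon, lat).

    Points outside the raster extent (beyond half a cell from the border)
    are flagged in_extent=False with no value.
    """
    lat = voltinism["lat"].to_numpy()
    lon = voltinism["lon"].to_numpy()
    half_dlat = np.abs(np.diff(lat)).max() / 2.0 if lat.size > 1 else np.inf
    half_dlon = np.abs(np.diff(lon)).max() / 2.0 if lon.size > 1 else np.inf
    rows = []
    for rec in points.itertuples(index=False):
        inside = (
            lat.min() - half_dlat <= rec.lat <= lat.max() + half_dlat
            and lon.min() - half_dlon <= rec.lon <= lon.max() + half_dlon
        )
        if inside:
            val = float(
                voltinism.sel(lat=rec.lat, lon=rec.lon, method="nearest").values
            )
        else:
            val = np.nan
        rows.append((rec.id, rec.lon, rec.lat, val, inside))
    return pd.DataFrame(rows, columns=["point_id", "lon", "lat", "generations", "in_extent"])


# ---------------------------------------------------------------------------
# raster I/O (NetCDF via xarray's scipy backend; CF-style degC layers)
# ---------------------------------------------------------------------------

def write_raster(raster: xr.DataArray, path, scale_factor: float | None = None) -> None:
    """Write a raster to NetCDF3.

    scale_factor packs values as integers (value = degC x 1/scale_factor),
    the dialect used by integer-packed climatology distributions
    (e.g. scale_factor=0.1 stores tenths of a degree).
    """
    da = raster
    if scale_factor is not None:
        packed = np.round(raster / scale_factor)
        packed = packed.where(np.isfinite(packed), -32768)
        da = packed.astype("int16")
        da.attrs = dict(raster.attrs, scale_factor=scale_factor, _FillValue=-32768)
        da.name = raster.name
    da.to_netcdf(path, engine="scipy")


def read_raster(path, var: str | None = None) -> xr.DataArray:
    """Read a raster written by write_raster, unpacking scale factors."""
    ds = xr.open_dataset(path, engine="scipy", mask_and_scale=True)
    name = var or list(ds.data_vars)[0]
    da = ds[name].load()
    ds.close()
    return da
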