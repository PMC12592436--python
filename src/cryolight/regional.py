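"""Regional aggregation and threshold metrics for the two study ecosystems.

Region masks for the Northern Bering–Chukchi and Barents large marine
ecosystems (LMEs) are shipped as approximate lon/lat boxes; user-supplied
boolean masks on the same grid are accepted everywhere a mask is taken.
Area weights follow dA = R^2 dphi dlambda cos(phi) with R = 6371 km.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM",
    "RegionMask",
    "lme_mask",
    "cell_area",
    "area_weighted_mean",
    "rolling_mean",
    "decadal_monthly_anomaly",
    "months_above_threshold",
    "open_water_fraction",
    "area_above_light",
]

EARTH_RADIUS_KM = 6371.0

#: approximate lon/lat boxes for the two LMEs (lon in 0–360)
_LME_BOXES = {
    "northern-bering-chukchi": {"lat": (62.0, 75.0), "lon": (178.0, 205.0), "center_lat": 69.5},
    "barents": {"lat": (68.0, 80.0), "lon": (20.0, 55.0), "center_lat": 75.0},
}


@dataclass
class RegionMask:
    name: str
    mask: xr.DataArray  # boolean (lat, lon)
    center_lat: float

    def __post_init__(self):
        if not bool(self.mask.any()):
            raise ValueError(f"region mask {self.name!r} is empty")


def lme_mask(name: str, lat: np.ndarray, lon: np.ndarray) -> RegionMask:
    """Boolean mask for a named LME box on the given grid."""
    key = name.lower().replace(" ", "-")
    if key not in _LME_BOXES:
        raise ValueError(f"unknown region {name!r}; expected one of {sorted(_LME_BOXES)}")
    box = _LME_BOXES[key]
    lat = np.asarray(lat, dtype=float)
    lon = np.mod(np.asarray(lon, dtype=float), 360.0)
    m = (
        (lat[:, None] >= box["lat"][0]) & (lat[:, None] <= box["lat"][1])
        & (lon[None, :] >= box["lon"][0]) & (lon[None, :] <= box["lon"][1])
    )
    da = xr.DataArray(m, coords={"lat": lat, "lon": np.asarray(lon)}, dims=("lat", "lon"))
    return RegionMask(name=key, mask=da, center_lat=box["center_lat"])


def cell_area(lat_deg, dlat_deg: float = 1.0, dlon_deg: float = 1.0):
    """Cell area (km^2): R^2 dphi dlambda cos(phi), angles in radians."""
    lat = np.asarray(lat_deg, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range")
    return (
        EARTH_RADIUS_KM**2
        * np.deg2rad(dlat_deg)
        * np.deg2rad(dlon_deg)
        * np.clip(np.cos(np.deg2rad(lat)), 0.0, None)
    )


def _weights(field: xr.DataArray) -> xr.DataArray:
    lat = field.lat.values
    dlat = float(np.median(np.diff(lat))) if lat.size > 1 else 1.0
    lon = field.lon.values
    dlon = float(np.median(np.diff(lon))) if lon.size > 1 else 1.0
    w = cell_area(lat, dlat, dlon)
    return xr.DataArray(w, coords={"lat": field.lat}, dims=("lat",))


def area_weighted_mean(field: xr.DataArray, mask: RegionMask | xr.DataArray) -> xr.DataArray:
    """Area-weighted mean over a region; reduces lat/lon, keeps other dims."""
    m = mask.mask if isinstance(mask, RegionMask) else mask
    sub = field.where(m)
    if not bool(np.isfinite(sub).any()):
        raise ValueError("all cells masked or missing in the region")
    return sub.weighted(_weights(field).broadcast_like(m).where(m, 0.0)).mean(("lat", "lon"))


def rolling_mean(series: xr.DataArray | pd.Series, window_years: int = 5) -> xr.DataArray | pd.Series:
    """Centered rolling mean in time; edges average the available points."""
    if isinstance(series, pd.Series):
        return series.rolling(window_years, center=True, min_periods=1).mean()
    return series.rolling(time=window_years, center=True, min_periods=1).mean()


def decadal_monthly_anomaly(
    series: pd.Series, baseline: tuple[int, int] = (1980, 2000)
) -> pd.DataFrame:
    """Month-by-decade anomaly table relative to a baseline monthly
    climatology.

    The first column holds the baseline monthly means; each later column is
    one decade's monthly mean minus the baseline.  ``series`` must be a
    monthly time series indexed by timestamps covering the baseline.
    """
    s = pd.Series(series).dropna()
    idx = pd.DatetimeIndex(s.index)
    base = s[(idx.year >= baseline[0]) & (idx.year <= baseline[1])]
    if base.empty:
        raise ValueError("series does not cover the baseline period")
    base_clim = base.groupby(pd.DatetimeIndex(base.index).month).mean()

    decades = sorted({(y // 10) * 10 for y in idx.year if y > baseline[1]})
    cols = {f"{baseline[0]}-{baseline[1]}": base_clim}
    for dec in decades:
        part = s[(idx.year >= dec) & (idx.year <= dec + 9)]
        if part.empty:
            continue
        clim = part.groupby(pd.DatetimeIndex(part.index).month).mean()
        cols[f"{dec}s"] = clim - base_clim
    out = pd.DataFrame(cols)
    out.index.name = "month"
    return out


_HALF_YEARS = {"winter-spring": (1, 6), "summer-fall": (7, 12)}


def months_above_threshold(series: pd.Series, threshold: float, half_year: str) -> pd.Series:
    """Fractional months per year above a threshold within a half-year.

    Between adjacent month centers the series is treated as linear, so a
    crossing contributes a fractional month; a year with missing months is
    skipped with a warning.
    """
    if half_year not in _HALF_YEARS:
        raise ValueError(f"half_year must be one of {sorted(_HALF_YEARS)}")
    lo, hi = _HALF_YEARS[half_year]
    s = pd.Series(series)
    idx = pd.DatetimeIndex(s.index)
    out = {}
    for year, grp in s.groupby(idx.year):
        if grp.size != 12 or grp.isna().any():
            logger.warning("year %d incomplete; skipped", year)
            continue
        months = np.asarray(grp.values, dtype=float)[lo - 1 : hi]
        out[year] = _duration_above(months, threshold)
    return pd.Series(out, name=f"months_above_{threshold}")


def _duration_above(months: np.ndarray, threshold: float) -> float:
    """Length (months) of the half-year where the piecewise-linear
    interpolant through the month-center values exceeds the threshold.

    Each month center carries a flat half-month on the outer edges, so six
    above-threshold months yield 6.0 and a threshold crossing inside an
    interval yields the interpolated fraction of that interval.
    """
    above = months > threshold
    total = 0.5 * above[0] + 0.5 * above[-1]
    for k in range(len(months) - 1):
        a, b = months[k], months[k + 1]
        if above[k] and above[k + 1]:
            total += 1.0
        elif above[k] != above[k + 1]:
            total += abs((max(a, b) - threshold) / (a - b))
    return float(total)


def open_water_fraction(
    siconc: xr.DataArray, mask: RegionMask | xr.DataArray, cutoff: float = 0.15
) -> xr.DataArray:
    """Area fraction of the region with sea-ice concentration below
    ``cutoff`` (open-water convention)."""
    m = mask.mask if isinstance(mask, RegionMask) else mask
    w = _weights(siconc).broadcast_like(m).where(m, 0.0)
    is_open = (siconc < cutoff).where(np.isfinite(siconc))
    return is_open.weighted(w).mean(("lat", "lon"))


def area_above_light(
    par: xr.DataArray, mask: RegionMask | xr.DataArray, threshold: float = 0.1
) -> xr.DataArray:
    """Total area (km^2) of the region where PAR exceeds ``threshold``."""
    m = mask.mask if isinstance(mask, RegionMask) else mask
    w = _weights(par).broadcast_like(m).where(m, 0.0)
    hit = (par > threshold).astype(float).where(np.isfinite(par), 0.0)
    return (hit * w).sum(("lat", "lon"))
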