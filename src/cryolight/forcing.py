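"""Monthly gridded climate forcing fields for the radiative transfer model.

Twelve CMIP6-named variables drive the model (tas, siconc, sisnthick, chl,
sithick, sisnconc, clt, uas, vas, toz, tos, prw).  Internally all fields live
on a regular lon/lat grid as ``xarray.DataArray`` objects with a monthly time
axis (stamped on the 15th of each month), with fraction variables in [0, 1]
and temperatures in degrees Celsius.  Unit conversion from common CMIP6
conventions (percent fractions, Kelvin temperatures) happens at the I/O
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "Grid1x1",
    "ForcingField",
    "VARIABLES",
    "FRACTION_VARS",
    "TEMPERATURE_VARS",
    "FormatError",
    "SpliceError",
    "read_forcing",
    "write_forcing",
    "regrid_bilinear",
    "concat_scenarios",
    "validate_field",
    "wind_speed",
]

#: internal units and physical bounds per variable
VARIABLES = {
    "tas": {"units": "degC", "min": -90.0, "max": 60.0},
    "tos": {"units": "degC", "min": -2.5, "max": 45.0},
    "siconc": {"units": "1", "min": 0.0, "max": 1.0},
    "sisnconc": {"units": "1", "min": 0.0, "max": 1.0},
    "clt": {"units": "1", "min": 0.0, "max": 1.0},
    "sithick": {"units": "m", "min": 0.0, "max": None},
    "sisnthick": {"units": "m", "min": 0.0, "max": None},
    "chl": {"units": "mg m-3", "min": 0.0, "max": None},
    "toz": {"units": "DU", "min": 1e-6, "max": None},
    "prw": {"units": "kg m-2", "min": 0.0, "max": None},
    "uas": {"units": "m s-1", "min": None, "max": None},
    "vas": {"units": "m s-1", "min": None, "max": None},
}

FRACTION_VARS = frozenset({"siconc", "sisnconc", "clt"})
TEMPERATURE_VARS = frozenset({"tas", "tos"})


class FormatError(ValueError):
    """A forcing file or field does not meet the expected layout."""


class SpliceError(ValueError):
    """Historical and future segments cannot be concatenated."""


@dataclass(frozen=True)
class Grid1x1:
    """Regular lon/lat grid, cell centers on integer degrees.

    Defaults to the polar study domain: 60–85°N, 0–359°E, 1° spacing.
    """

    lat: np.ndarray = field(default_factory=lambda: np.arange(60.0, 86.0, 1.0))
    lon: np.ndarray = field(default_factory=lambda: np.arange(0.0, 360.0, 1.0))

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        if lat.size < 1 or lon.size < 1:
            raise ValueError("empty grid")
        if lat.size > 1 and not np.all(np.diff(lat) > 0):
            raise ValueError("latitudes must be strictly increasing")
        if lon.size > 1 and not np.all(np.diff(lon) > 0):
            raise ValueError("longitudes must be strictly increasing")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)


@dataclass
class ForcingField:
    """One forcing variable on a regular grid with monthly timestamps."""

    variable_id: str
    data: xr.DataArray  # dims (time, lat, lon)
    scenario: str = "historical"
    model_id: str = "SYNTH"
    realization_id: str = "r1i1p1f1"

    def __post_init__(self):
        if self.variable_id not in VARIABLES:
            raise FormatError(f"unknown variable_id {self.variable_id!r}")
        missing = {"time", "lat", "lon"} - set(self.data.dims)
        if missing:
            raise FormatError(f"field missing dims {sorted(missing)}")

    @property
    def grid(self) -> Grid1x1:
        return Grid1x1(self.data.lat.values, self.data.lon.values)

    def sel_cell(self, lat: float, lon: float) -> xr.DataArray:
        return self.data.sel(lat=lat, lon=lon, method="nearest")


def _monthly_time_ok(time_values) -> bool:
    t = pd.DatetimeIndex(time_values)
    if len(t) == 0:
        return False
    if len(t) == 1:
        return True
    per = t.to_period("M")
    diffs = (per[1:] - per[:-1]).map(lambda d: d.n)
    return bool(np.all(np.asarray(diffs) == 1))


def validate_field(ff: ForcingField) -> None:
    """Raise if a field violates its physical invariants.

    Missing cells (NaN) are allowed — they are flagged and skipped downstream,
    never silently filled.
    """
    spec = VARIABLES[ff.variable_id]
    vals = ff.data.values
    finite = vals[np.isfinite(vals)]
    if finite.size:
        if spec["min"] is not None and finite.min() < spec["min"] - 1e-9:
            raise ValueError(
                f"{ff.variable_id}: value {finite.min():.4g} below bound {spec['min']}"
            )
        if spec["max"] is not None and finite.max() > spec["max"] + 1e-9:
            raise ValueError(
                f"{ff.variable_id}: value {finite.max():.4g} above bound {spec['max']}"
            )
    if not _monthly_time_ok(ff.data.time.values):
        raise FormatError(f"{ff.variable_id}: time axis is not strictly monthly")


def _normalize_units(variable_id: str, da: xr.DataArray) -> xr.DataArray:
    units = str(da.attrs.get("units", "")).strip()
    vals = da
    if variable_id in FRACTION_VARS:
        finite_max = float(np.nanmax(vals.values)) if np.isfinite(vals).any() else 0.0
        if units == "%" or finite_max > 1.5:
            vals = vals / 100.0
    elif variable_id in TEMPERATURE_VARS:
        finite = vals.values[np.isfinite(vals.values)]
        if units.upper().startswith("K") or (finite.size and finite.min() > 100.0):
            vals = vals - 273.15
    vals = vals.assign_attrs(units=VARIABLES[variable_id]["units"])
    return vals


def read_forcing(path, variable_id: str) -> ForcingField:
    """Read one forcing variable from a CF-style NetCDF file.

    Accepts ``latitude``/``longitude`` coordinate spellings, normalizes units
    to internal conventions, and rejects non-monthly time axes.
    """
    if variable_id not in VARIABLES:
        raise FormatError(f"unknown variable_id {variable_id!r}")
    try:
        ds = xr.open_dataset(path)
    except FileNotFoundError:
        raise
    with ds:
        if variable_id not in ds:
            raise FormatError(f"variable {variable_id!r} not found in {path}")
        da = ds[variable_id]
        rename = {}
        for cand, target in (("latitude", "lat"), ("longitude", "lon")):
            if cand in da.dims:
                rename[cand] = target
        if rename:
            da = da.rename(rename)
        missing = {"time", "lat", "lon"} - set(da.dims)
        if missing:
            raise FormatError(f"{path}: missing coordinates {sorted(missing)}")
        if not _monthly_time_ok(da.time.values):
            raise FormatError(f"{path}: time axis is not monthly")
        da = _normalize_units(variable_id, da).transpose("time", "lat", "lon").load()
    attrs = ds.attrs
    return ForcingField(
        variable_id=variable_id,
        data=da,
        scenario=attrs.get("scenario", "historical"),
        model_id=attrs.get("model_id", da.attrs.get("model_id", "UNKNOWN")),
        realization_id=attrs.get("realization_id", "r1i1p1f1"),
    )


def write_forcing(ff: ForcingField, path) -> None:
    """Write a forcing field as NetCDF (classic format, scipy backend)."""
    ds = ff.data.to_dataset(name=ff.variable_id)
    ds.attrs.update(
        scenario=ff.scenario, model_id=ff.model_id, realization_id=ff.realization_id
    )
    ds.to_netcdf(path, engine="scipy")


# --------------------------------------------------------------------------
# regridding

def _bracket(src: np.ndarray, tgt: np.ndarray):
    """Indices (i0, i1) and weight of the upper neighbor for 1-D linear
    interpolation of ``tgt`` inside ``src`` (no extrapolation)."""
    i1 = np.searchsorted(src, tgt)
    i1 = np.clip(i1, 1, src.size - 1)
    i0 = i1 - 1
    w = (tgt - src[i0]) / (src[i1] - src[i0])
    return i0, i1, np.clip(w, 0.0, 1.0)


def regrid_bilinear(ff: ForcingField, target: Grid1x1) -> ForcingField:
    """Bilinear interpolation onto ``target`` with longitude wraparound.

    Missing (NaN) source cells contribute nothing; the remaining corner
    weights are renormalized, so coastal cells keep valid values instead of
    being eaten by the mask.  Raises if the target latitudes are outside the
    source latitude span.
    """
    src_lat = ff.data.lat.values.astype(float)
    src_lon = ff.data.lon.values.astype(float)
    if target.lat.min() < src_lat.min() - 1e-9 or target.lat.max() > src_lat.max() + 1e-9:
        raise ValueError("target latitudes outside source latitude span")

    # wrap longitude: append the first column at lon+360
    lon_ext = np.concatenate([src_lon, src_lon[:1] + 360.0])
    vals = ff.data.values.astype(float)
    vals_ext = np.concatenate([vals, vals[:, :, :1]], axis=2)

    tgt_lon = np.mod(target.lon, 360.0)
    tgt_lon = np.where(tgt_lon < lon_ext[0], tgt_lon + 360.0, tgt_lon)

    j0, j1, wy = _bracket(src_lat, target.lat)
    k0, k1, wx = _bracket(lon_ext, tgt_lon)

    wy = wy[:, None]
    wx = wx[None, :]
    corners = [
        (vals_ext[:, j0][:, :, k0], (1 - wy) * (1 - wx)),
        (vals_ext[:, j0][:, :, k1], (1 - wy) * wx),
        (vals_ext[:, j1][:, :, k0], wy * (1 - wx)),
        (vals_ext[:, j1][:, :, k1], wy * wx),
    ]
    num = np.zeros((vals.shape[0], target.lat.size, target.lon.size))
    den = np.zeros_like(num)
    for v, w in corners:
        ok = np.isfinite(v)
        num += np.where(ok, v, 0.0) * w
        den += ok * w
    out = np.where(den > 1e-12, num / np.where(den > 0, den, 1.0), np.nan)

    da = xr.DataArray(
        out,
        dims=("time", "lat", "lon"),
        coords={"time": ff.data.time.values, "lat": target.lat, "lon": target.lon},
        attrs=ff.data.attrs,
    )
    return ForcingField(ff.variable_id, da, ff.scenario, ff.model_id, ff.realization_id)


# --------------------------------------------------------------------------
# scenario splicing

def concat_scenarios(historical: ForcingField, future: ForcingField) -> ForcingField:
    """Concatenate a historical segment with a future scenario segment.

    The historical series must end exactly one month before the future one
    begins, on the same grid, for the same variable/model/realization.
    """
    for attr in ("variable_id", "model_id", "realization_id"):
        if getattr(historical, attr) != getattr(future, attr):
            raise SpliceError(f"mismatched {attr}")
    if not (
        np.array_equal(historical.data.lat.values, future.data.lat.values)
        and np.array_equal(historical.data.lon.values, future.data.lon.values)
    ):
        raise SpliceError("mismatched grids")
    last = pd.Timestamp(historical.data.time.values[-1]).to_period("M")
    first = pd.Timestamp(future.data.time.values[0]).to_period("M")
    if (first - last).n != 1:
        raise SpliceError(
            f"historical ends {last}, future begins {first}: segments must be contiguous"
        )
    da = xr.concat([historical.data, future.data], dim="time")
    return ForcingField(
        historical.variable_id,
        da,
        scenario=future.scenario,
        model_id=historical.model_id,
        realization_id=historical.realization_id,
    )


def wind_speed(uas: xr.DataArray, vas: xr.DataArray) -> xr.DataArray:
    """Scalar wind speed from eastward/northward components."""
    return np.hypot(uas, vas).assign_attrs(units="m s-1")
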