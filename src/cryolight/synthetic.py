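"""Synthetic monthly forcing fields emulating polar CMIP6 output.

The generator produces the 12 forcing variables on a regular grid with
latitude-dependent seasonal cycles, scenario-dependent linear trends (warming
air and ocean, declining ice/snow, recovering ozone), a spring chlorophyll
bloom whose peak advances over the decades, and optional white noise.  It is
the test harness for the radiative transfer pipeline; it stands in for the
real climate-model archives and makes no attempt to reproduce their spatial
structure beyond a smooth latitudinal gradient.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .forcing import FRACTION_VARS, ForcingField, Grid1x1, VARIABLES

logger = logging.getLogger(__name__)

__all__ = ["SyntheticForcingConfig", "generate_synthetic_forcing", "SCENARIO_TRENDS"]

#: linear trends per century, by scenario (units of each variable per 100 yr)
SCENARIO_TRENDS = {
    "historical": {
        "tas": 1.0, "tos": 0.5, "siconc": -0.10, "sithick": -0.30,
        "sisnthick": -0.05, "sisnconc": -0.05, "clt": 0.0, "toz": 5.0,
        "prw": 1.0, "chl_rel": 0.0,
    },
    "SSP2-4.5": {
        "tas": 3.0, "tos": 2.0, "siconc": -0.35, "sithick": -1.0,
        "sisnthick": -0.15, "sisnconc": -0.20, "clt": 0.0, "toz": 20.0,
        "prw": 2.0, "chl_rel": 0.05,
    },
    "SSP5-8.5": {
        "tas": 6.0, "tos": 4.0, "siconc": -0.60, "sithick": -1.6,
        "sisnthick": -0.25, "sisnconc": -0.35, "clt": 0.02, "toz": 50.0,
        "prw": 4.0, "chl_rel": -0.05,
    },
}


@dataclass
class SyntheticForcingConfig:
    """Controls for the synthetic forcing generator.

    ``trend_overrides`` replaces individual per-century trends from
    :data:`SCENARIO_TRENDS`; ``bloom_advance_days_per_decade`` moves the
    spring chlorophyll peak earlier each decade; ``noise_sd`` is a relative
    perturbation amplitude (0 disables noise entirely).
    """

    scenario: str = "SSP2-4.5"
    start_year: int = 1979
    end_year: int = 2100
    seed: int = 0
    noise_sd: float = 0.03
    bloom_advance_days_per_decade: float = 3.0
    trend_overrides: dict = field(default_factory=dict)
    grid: Grid1x1 = field(default_factory=Grid1x1)
    model_id: str = "SYNTH"
    realization_id: str = "r1i1p1f1"

    def trends(self) -> dict:
        if self.scenario not in SCENARIO_TRENDS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {sorted(SCENARIO_TRENDS)}"
            )
        t = dict(SCENARIO_TRENDS[self.scenario])
        t.update(self.trend_overrides)
        return t


def _monthly_index(start_year: int, end_year: int) -> pd.DatetimeIndex:
    # timestamps on the 15th of each month, matching the RTM sampling day
    months = pd.period_range(f"{start_year}-01", f"{end_year}-12", freq="M")
    return pd.DatetimeIndex([p.to_timestamp() + pd.Timedelta(days=14) for p in months])


def _seasonal(month, peak_month, amplitude):
    """Cosine seasonal cycle peaking at ``peak_month`` (1..12)."""
    return amplitude * np.cos(2.0 * np.pi * (month - peak_month) / 12.0)


def generate_synthetic_forcing(config: SyntheticForcingConfig) -> dict[str, ForcingField]:
    """Generate the full 12-variable forcing set.

    Returns a dict keyed by variable_id.  Fields satisfy all forcing
    invariants; values pushed out of range by trends are clamped (with a
    logged warning for fraction variables).
    """
    trends = config.trends()
    time = _monthly_index(config.start_year, config.end_year)
    lat = config.grid.lat
    lon = config.grid.lon
    rng = np.random.default_rng(config.seed)

    month = np.array([t.month for t in time], dtype=float)[:, None, None]
    years = np.array(
        [t.year + (t.dayofyear - 1) / 365.25 for t in time], dtype=float
    )[:, None, None]
    t100 = (years - config.start_year) / 100.0  # centuries since series start
    latg = lat[None, :, None]
    long_ = lon[None, None, :]
    # mild zonal texture so longitudes are not strictly identical
    zonal = 0.03 * np.cos(np.deg2rad(long_ * 2.0))

    fields: dict[str, np.ndarray] = {}

    # --- temperatures ------------------------------------------------------
    fields["tas"] = (
        4.0 - 0.9 * (latg - 60.0)
        + _seasonal(month, 7.5, 12.0)
        + trends["tas"] * t100
        + 5.0 * zonal
    )
    tos_raw = (
        5.0 - 0.45 * (latg - 60.0)
        + _seasonal(month, 8.0, 4.0)
        + trends["tos"] * t100
        + 2.0 * zonal
    )
    fields["tos"] = np.maximum(tos_raw, -1.8)

    # --- sea ice and snow --------------------------------------------------
    ice_base = np.clip((latg - 63.0) / 12.0, 0.0, 1.0) + 0.0 * month
    ice_season = 0.55 + 0.45 * np.cos(2.0 * np.pi * (month - 3.0) / 12.0)  # max Mar, min Sep
    fields["siconc"] = ice_base * ice_season + trends["siconc"] * t100
    fields["sithick"] = (
        2.2 * ice_base * (0.65 + 0.35 * np.cos(2.0 * np.pi * (month - 4.0) / 12.0))
        + trends["sithick"] * t100 * ice_base
    )
    snow_season = np.clip(np.cos(2.0 * np.pi * (month - 2.0) / 12.0), 0.0, None)
    fields["sisnthick"] = (
        0.35 * ice_base * snow_season + trends["sisnthick"] * t100 * ice_base
    )
    fields["sisnconc"] = (
        0.9 * np.clip(fields["sisnthick"] / 0.10, 0.0, 1.0)
        + trends["sisnconc"] * t100 * ice_base
    )

    # --- chlorophyll bloom -------------------------------------------------
    # spring bloom peak month, later at higher latitude, advancing with time
    advance_months = (
        config.bloom_advance_days_per_decade * (years - config.start_year) / 10.0 / 30.4
    )
    bloom_center = 5.5 + 0.05 * (latg - 60.0) - advance_months
    peak = 3.0 * (1.0 + trends["chl_rel"] * t100)  # chl_rel: relative change per century
    fields["chl"] = 0.15 + peak * np.exp(-(((month - bloom_center) / 0.9) ** 2))

    # --- atmosphere --------------------------------------------------------
    fields["clt"] = (
        0.82 + 0.05 * np.cos(2.0 * np.pi * (month - 10.0) / 12.0)
        + trends["clt"] * t100 + zonal
    )
    fields["toz"] = (
        330.0 + 0.4 * (latg - 60.0)
        + _seasonal(month, 3.5, 40.0)
        + trends["toz"] * t100
    )
    fields["prw"] = np.clip(
        6.0 - 0.15 * (latg - 60.0) + _seasonal(month, 7.5, 4.0) + trends["prw"] * t100,
        0.2,
        None,
    )
    fields["uas"] = 4.0 + _seasonal(month, 1.0, 1.5) + 0.0 * latg
    fields["vas"] = 1.0 + _seasonal(month, 12.0, 1.0) + 0.0 * latg

    # --- noise and clamping ------------------------------------------------
    scales = {
        "tas": 1.5, "tos": 0.7, "siconc": 0.05, "sithick": 0.15, "sisnthick": 0.03,
        "sisnconc": 0.05, "chl": 0.3, "clt": 0.04, "toz": 8.0, "prw": 0.8,
        "uas": 1.0, "vas": 1.0,
    }
    out: dict[str, ForcingField] = {}
    for var, arr in fields.items():
        arr = np.broadcast_to(arr, (time.size, lat.size, lon.size)).copy()
        if config.noise_sd > 0:
            arr += rng.normal(0.0, config.noise_sd * scales[var], size=arr.shape)
        spec = VARIABLES[var]
        lo = spec["min"] if spec["min"] is not None else -np.inf
        hi = spec["max"] if spec["max"] is not None else np.inf
        if var in FRACTION_VARS and (np.any(arr < lo) or np.any(arr > hi)):
            logger.warning("synthetic %s clamped to [0, 1] (trend/noise overshoot)", var)
        arr = np.clip(arr, lo, hi)
        da = xr.DataArray(
            arr,
            dims=("time", "lat", "lon"),
            coords={"time": time, "lat": lat, "lon": lon},
            attrs={"units": spec["units"]},
        )
        out[var] = ForcingField(
            variable_id=var,
            data=da,
            scenario=config.scenario,
            model_id=config.model_id,
            realization_id=config.realization_id,
        )
    return out


def pseudo_observations(config: SyntheticForcingConfig, seed_offset: int = 101) -> dict[str, ForcingField]:
    """A perturbed generator run usable as pseudo-observations when testing
    the ensemble-weighting pipeline without real observational datasets."""
    cfg = replace(
        config,
        seed=config.seed + seed_offset,
        model_id="PSEUDO-OBS",
        realization_id="obs",
    )
    return generate_synthetic_forcing(cfg)
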