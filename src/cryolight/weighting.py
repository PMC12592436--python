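"""Performance-and-independence weighting of a climate-model ensemble.

Each model is scored by its distance to observations (performance) and its
distances to the other models (independence) over three diagnostics of sea
surface temperature — climatological mean, linear trend, and detrended
interannual standard deviation — computed per cell and combined as
area-weighted RMSEs normalized by the ensemble median of each diagnostic.

The raw weight of model i is

    w_i = exp(-D_i^2 / sigma_D^2) / (1 + sum_{j != i} exp(-S_ij^2 / sigma_S^2))

and the final weights are normalized to sum to one.  Multiple realizations of
one model are averaged before distances are computed, so near-duplicate
ensemble members are penalized rather than double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .forcing import ForcingField
from .regional import cell_area

__all__ = [
    "Diagnostics",
    "compute_diagnostics",
    "compute_distances",
    "compute_weights",
    "weighted_ensemble_mean",
    "weights_table",
]


@dataclass
class Diagnostics:
    """Per-cell climatology, linear trend, and detrended std of one field."""

    climatology: xr.DataArray  # (lat, lon)
    trend: xr.DataArray        # per year
    std: xr.DataArray


def compute_diagnostics(field: ForcingField, window: tuple[int, int] | None = None) -> Diagnostics:
    """Climatology, least-squares linear trend (per year), and detrended
    standard deviation of a monthly field over ``window`` (inclusive years).

    Requires at least 10 years of data in the window.
    """
    da = field.data
    time = pd.DatetimeIndex(da.time.values)
    if window is not None:
        keep = (time.year >= window[0]) & (time.year <= window[1])
        da = da.isel(time=np.nonzero(keep)[0])
        time = time[keep]
    if time.size < 120:
        raise ValueError("diagnostics window must contain at least 10 years of monthly data")

    # month-center year fractions: uniform phase sampling, immune to
    # leap-year day-count jitter
    years = np.asarray(time.year + (time.month - 0.5) / 12.0, dtype=float)
    vals = da.values  # (n, lat, lon)
    clim = np.nanmean(vals, axis=0)
    anom = vals - clim

    # fit the linear trend to annual means so the seasonal cycle cannot
    # leak into the slope, then detrend the monthly anomalies with it
    year_labels = np.asarray(time.year)
    uniq = np.unique(year_labels)
    annual = np.stack([np.nanmean(anom[year_labels == y], axis=0) for y in uniq])
    ty = uniq + 0.5 - (uniq + 0.5).mean()
    trend = np.nansum(annual * ty[:, None, None], axis=0) / np.sum(ty**2)

    t = years - years.mean()
    detrended = anom - trend * t[:, None, None]
    std = np.nanstd(detrended, axis=0, ddof=1)

    coords = {"lat": da.lat, "lon": da.lon}
    return Diagnostics(
        climatology=xr.DataArray(clim, coords=coords, dims=("lat", "lon")),
        trend=xr.DataArray(trend, coords=coords, dims=("lat", "lon")),
        std=xr.DataArray(std, coords=coords, dims=("lat", "lon")),
    )


def _area_rmse(a: xr.DataArray, b: xr.DataArray) -> float:
    lat = a.lat.values
    w2d = np.broadcast_to(
        cell_area(lat, 1.0, 1.0)[:, None], a.shape
    )
    diff2 = (a.values - b.values) ** 2
    ok = np.isfinite(diff2)
    if not ok.any():
        raise ValueError("no overlapping valid cells")
    return float(np.sqrt(np.sum(diff2[ok] * w2d[ok]) / np.sum(w2d[ok])))


def _combined_distance(d1: Diagnostics, d2: Diagnostics) -> np.ndarray:
    return np.array(
        [
            _area_rmse(d1.climatology, d2.climatology),
            _area_rmse(d1.trend, d2.trend),
            _area_rmse(d1.std, d2.std),
        ]
    )


def compute_distances(
    model_diags: dict[str, Diagnostics], obs_diags: Diagnostics
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Distances to observations D_i and between models S_ij.

    ``model_diags`` maps model_id to its (realization-averaged) diagnostics.
    Per-diagnostic RMSEs are normalized by the ensemble median of that
    diagnostic's D before averaging across the three diagnostics; the same
    normalization is applied to S.  Returns (D, S, model_ids).
    """
    ids = sorted(model_diags)
    m = len(ids)
    d_raw = np.array([_combined_distance(model_diags[k], obs_diags) for k in ids])  # (m, 3)
    s_raw = np.zeros((m, m, 3))
    for i in range(m):
        for j in range(i + 1, m):
            s = _combined_distance(model_diags[ids[i]], model_diags[ids[j]])
            s_raw[i, j] = s
            s_raw[j, i] = s

    norm = np.median(d_raw, axis=0)
    norm = np.where(norm > 0, norm, 1.0)
    d = (d_raw / norm).mean(axis=1)
    s_mat = (s_raw / norm).mean(axis=2)
    np.fill_diagonal(s_mat, 0.0)
    return d, s_mat, ids


def average_realizations(diags: dict[tuple[str, str], Diagnostics]) -> dict[str, Diagnostics]:
    """Average diagnostics across realizations of the same model."""
    by_model: dict[str, list[Diagnostics]] = {}
    for (model_id, _real), dg in diags.items():
        by_model.setdefault(model_id, []).append(dg)
    out = {}
    for model_id, lst in by_model.items():
        out[model_id] = Diagnostics(
            climatology=sum(d.climatology for d in lst) / len(lst),
            trend=sum(d.trend for d in lst) / len(lst),
            std=sum(d.std for d in lst) / len(lst),
        )
    return out


def compute_weights(
    d: np.ndarray,
    s: np.ndarray,
    sigma_d: float | None = None,
    sigma_s: float | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Skill-and-independence weights.

    ``sigma_d``/``sigma_s`` default to the ensemble median of D and of the
    off-diagonal S respectively (they control how sharply performance and
    similarity are penalized); pass explicit values to override.
    """
    d = np.asarray(d, dtype=float)
    s = np.asarray(s, dtype=float)
    m = d.size
    if s.shape != (m, m):
        raise ValueError("S must be an MxM matrix matching D")
    if not np.allclose(s, s.T) or not np.allclose(np.diag(s), 0.0):
        raise ValueError("S must be symmetric with a zero diagonal")
    if sigma_d is None:
        med = float(np.median(d))
        sigma_d = med if med > 0 else 1.0
    if sigma_s is None:
        off = s[~np.eye(m, dtype=bool)]
        med = float(np.median(off)) if off.size else 1.0
        sigma_s = med if med > 0 else 1.0
    if sigma_d <= 0 or sigma_s <= 0:
        raise ValueError("shape parameters must be positive")

    perf = np.exp(-(d**2) / sigma_d**2)
    # the zero diagonal of S contributes exp(0) = 1, exactly the leading
    # "1 +" of the independence denominator
    indep = np.exp(-(s**2) / sigma_s**2).sum(axis=1)
    w = perf / indep
    if normalize:
        w = w / w.sum()
    return w


def weighted_ensemble_mean(fields: list[xr.DataArray], weights: np.ndarray) -> xr.DataArray:
    """Weighted mean of per-model fields on a common grid."""
    weights = np.asarray(weights, dtype=float)
    if len(fields) != weights.size:
        raise ValueError("number of fields and weights must match")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    out = fields[0] * weights[0]
    for f, w in zip(fields[1:], weights[1:]):
        out = out + f * w
    return out


def weights_table(ids: list[str], d: np.ndarray, raw_w: np.ndarray, w: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"model_id": ids, "D": d, "raw_w": raw_w, "w": w})
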