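"""Surface albedo: open-ocean OSA scheme and sea-ice/snow parameterization.

Open water uses a spectral ocean-surface-albedo (OSA) scheme in the style of
next-generation climate-model parameterizations: Fresnel surface reflection
with Cox–Munk wind-slope facet averaging for the direct beam, a
wind-dependent hemispherically averaged term for diffuse light, a whitecap
fraction growing with wind speed, and a chlorophyll-dependent water-leaving
reflectance built from water/phytoplankton absorption and backscatter.

Sea ice and snow use broadband constants in the CICE/CCSM heritage: thick
bare ice 0.52, snow-covered ice 0.65, with a thin-ice arctangent blend toward
the open-ocean albedo and a melt-pond darkening that ramps in as near-surface
air temperature rises from -1 degC to 0 degC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tables
from .solar import SolarGeometry, SpectralGrid, extraterrestrial_spectrum

__all__ = [
    "AlbedoParams",
    "SurfaceState",
    "osa_spectral",
    "thin_ice_blend_fh",
    "ice_albedo_dry",
    "apply_melt_pond",
    "composite_cell_albedo",
    "broadband",
]


@dataclass
class AlbedoParams:
    """Constants of the ice/snow albedo parameterization.

    The thick-ice and snow-covered-ice values are annual averages that fold
    in seasonal surface deterioration away from pure conditions (pure ice
    0.73, pure snow 0.96, kept as metadata only).
    """

    a_ice_thick: float = 0.52
    a_snow_ice: float = 0.65
    c_fh: float = 5.0
    h_ref: float = 0.5          # m, thickness at which the blend saturates
    pond_dalb: float = 0.075    # maximum melt-pond albedo reduction
    pond_onset_T: float = -1.0  # degC, ramp start
    pond_on_snow: bool = True   # apply pond correction to snow-covered ice too
    a_ice_pure: float = 0.73    # metadata
    a_snow_pure: float = 0.96   # metadata


@dataclass
class SurfaceState:
    """Everything the albedo and attenuation steps need for one cell."""

    siconc: float
    sisnconc: float
    sithick: float
    sisnthick: float
    tas: float       # degC
    wind: float      # m s-1
    chl: float       # mg m-3


# --------------------------------------------------------------------------
# ocean surface albedo (OSA)

def _fresnel_unpolarized(n, cos_i):
    """Fresnel reflectance of unpolarized light at an air–water interface."""
    cos_i = np.clip(cos_i, 1e-6, 1.0)
    sin_t = np.clip(np.sqrt(1.0 - cos_i**2) / n, 0.0, 1.0)
    cos_t = np.sqrt(1.0 - sin_t**2)
    rs = ((cos_i - n * cos_t) / (cos_i + n * cos_t)) ** 2
    rp = ((n * cos_i - cos_t) / (n * cos_i + cos_t)) ** 2
    return 0.5 * (rs + rp)


def _refractive_index(wl_nm: np.ndarray) -> np.ndarray:
    # weak normal dispersion of sea water around n ~ 1.34
    return 1.325 + 6.0e3 / wl_nm**2 + 0.01 * (500.0 / wl_nm) ** 0.5


def _whitecap_fraction(wind):
    # whitecap coverage growing ~ u^1.59
    return np.clip(3.97e-4 * np.maximum(wind, 0.0) ** 1.59, 0.0, 0.3)


def _water_leaving(chl, grid: SpectralGrid, include_chl: bool):
    """Sub-surface (water-leaving) irradiance reflectance per wavelength."""
    a_w = tables.water_absorption()
    bbw = 0.00144 * (500.0 / grid.wavelengths) ** 4.32  # pure-seawater backscatter
    chl = np.maximum(np.asarray(chl, dtype=float), 0.0)[..., np.newaxis]
    if include_chl:
        a_ph = tables.phyto_specific_absorption() * chl
        bbp = 0.002 * chl**0.62
    else:
        a_ph = 0.0
        bbp = 0.0
    bb = bbw + bbp
    r_sub = 0.33 * bb / np.clip(a_w + a_ph + bb, 1e-9, None)
    # transmitted through the interface both ways
    return 0.96 * np.clip(r_sub, 0.0, 0.5)


def osa_spectral(
    geom: SolarGeometry,
    wind,
    chl,
    grid: SpectralGrid | None = None,
    include_chl: bool = True,
    include_wind: bool = True,
):
    """Spectral direct and diffuse open-ocean albedo.

    Returns ``(alpha_dir, alpha_diff)`` with wavelength on the last axis;
    zenith/wind/chl may be arrays (broadcast).  Direct albedo is nondecreasing
    in zenith angle; wind flattens the glint at grazing angles and adds
    whitecaps; chlorophyll modifies the water-leaving color term.
    """
    if np.any(np.asarray(wind) < 0):
        raise ValueError("wind speed must be nonnegative")
    if np.any(np.asarray(chl) < 0):
        raise ValueError("chlorophyll must be nonnegative")
    grid = grid or SpectralGrid()
    n = _refractive_index(grid.wavelengths)

    wind_eff = np.asarray(wind, dtype=float) if include_wind else np.zeros_like(
        np.asarray(wind, dtype=float)
    )
    zen = np.deg2rad(np.clip(np.asarray(geom.zenith_deg, dtype=float), 0.0, 89.9))

    # Cox–Munk mean-square slope; wave roughness damps the grazing-angle
    # glint (strongly at high zenith, negligibly near normal incidence)
    mss = 0.003 + 0.00512 * wind_eff
    sigma = np.sqrt(mss)
    damp = np.clip(1.0 - 2.0 * sigma * (zen / (np.pi / 2.0)) ** 3, 0.3, 1.0)
    a_dir_surf = _fresnel_unpolarized(n, np.cos(zen)[..., np.newaxis]) * damp[..., np.newaxis]

    # hemispherically averaged Fresnel term for diffuse light with a weak
    # wind-roughness reduction (Jin-style linear slope dependence)
    mu = np.linspace(0.01, 1.0, 50)
    r_diff = np.trapezoid(
        _fresnel_unpolarized(n[:, None], mu[None, :]) * 2.0 * mu[None, :], mu, axis=1
    )
    sigma = np.sqrt(mss)
    a_diff_surf = r_diff * (1.0 - 0.35 * sigma[..., np.newaxis])

    wc = _whitecap_fraction(wind_eff)[..., np.newaxis]
    a_wc = np.full(grid.wavelengths.shape, 0.22)  # flat whitecap albedo
    wl_term = _water_leaving(chl, grid, include_chl)

    alpha_dir = (1.0 - wc) * (a_dir_surf + wl_term) + wc * a_wc
    alpha_diff = (1.0 - wc) * (a_diff_surf + wl_term) + wc * a_wc
    return np.clip(alpha_dir, 0.0, 1.0), np.clip(alpha_diff, 0.0, 1.0)


def broadband(alpha_spectral: np.ndarray, grid: SpectralGrid | None = None) -> np.ndarray:
    """Solar-spectrum-weighted broadband albedo from a spectral albedo."""
    grid = grid or SpectralGrid()
    w = extraterrestrial_spectrum(grid)
    return (alpha_spectral * w).sum(axis=-1) / w.sum()


# --------------------------------------------------------------------------
# sea ice and snow

def thin_ice_blend_fh(h, c_fh: float = 5.0, h_ref: float = 0.5):
    """Arctangent thickness blend f_h = min(atan(c h)/atan(c h_ref), 1)."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("ice thickness must be nonnegative")
    return np.minimum(np.arctan(c_fh * h) / np.arctan(c_fh * h_ref), 1.0)


def ice_albedo_dry(h, a_o, params: AlbedoParams | None = None):
    """Dry (pond-free) bare-ice albedo blending open ocean toward thick ice:
    a_dry = a_o (1 - f_h) + 0.52 f_h."""
    params = params or AlbedoParams()
    fh = thin_ice_blend_fh(h, params.c_fh, params.h_ref)
    return np.asarray(a_o) * (1.0 - fh) + params.a_ice_thick * fh


def apply_melt_pond(a_dry, tas, params: AlbedoParams | None = None):
    """Melt-pond darkening: reduce albedo by up to 0.075, ramping linearly
    as air temperature rises from -1 degC to 0 degC."""
    params = params or AlbedoParams()
    ramp = np.clip(np.asarray(tas, dtype=float) - params.pond_onset_T, 0.0, 1.0)
    return np.clip(np.asarray(a_dry) - params.pond_dalb * ramp, 0.0, 1.0)


def composite_cell_albedo(
    state: SurfaceState,
    osa: np.ndarray,
    params: AlbedoParams | None = None,
    melt_ponds: bool = True,
):
    """Cell-mean spectral albedo combining open water, bare ice, and snow.

    alpha(lambda) = (1 - siconc) OSA(lambda)
                  + siconc [(1 - sisnconc) a_ice + sisnconc a_snow]

    where the ice/snow terms are broadband constants applied flat across the
    spectrum; sisnconc is the snow-covered fraction of the ice-covered area.
    """
    params = params or AlbedoParams()
    osa = np.asarray(osa, dtype=float)
    a_o = broadband(osa) if osa.ndim else float(osa)

    a_ice = ice_albedo_dry(state.sithick, a_o, params)
    a_snow = params.a_snow_ice
    if melt_ponds:
        a_ice = apply_melt_pond(a_ice, state.tas, params)
        if params.pond_on_snow:
            a_snow = apply_melt_pond(a_snow, state.tas, params)

    ice_part = (1.0 - state.sisnconc) * a_ice + state.sisnconc * a_snow
    return (1.0 - state.siconc) * osa + state.siconc * ice_part
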