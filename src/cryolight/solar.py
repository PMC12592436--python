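"""Solar geometry and clear-sky spectral irradiance.

The spectral model follows the structure of the Bird simple spectral model
(direct-normal and diffuse-horizontal irradiance built from multiplicative
transmittances for Rayleigh scattering, aerosol extinction, ozone and water
vapor absorption on a fixed 200–2700 nm grid).  Extraterrestrial irradiance is
a Planck spectrum at the solar effective temperature normalized to the total
solar irradiance; gas-absorption coefficients are parameterized band models
(Hartley/Huggins and Chappuis bands for ozone, near-infrared bands for water
vapor).  Coefficients live in :data:`SPECTRAL_DEFAULTS` and can be overridden.

Cloud adjustment treats a partly cloudy sky as a weighted average of the
clear sky and an overcast sky whose radiation is entirely diffuse; the
Campbell–Norman formulation provides the standalone diffuse fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralGrid",
    "SolarGeometry",
    "SpectralIrradiance",
    "OzoneProfile",
    "WAVELENGTHS_NM",
    "BANDS_NM",
    "solar_position",
    "sun_ephemeris",
    "zenith_from_hour_angle",
    "clearsky_spectral",
    "diffuse_fraction",
    "apply_cloud_opacity",
    "vmr_profile_to_dobson",
    "DOBSON_PER_PPM_HPA",
]

#: fixed wavelength grid, nm (251 bins of 10 nm)
WAVELENGTHS_NM = np.arange(200.0, 2701.0, 10.0)

#: band edges in nm, inclusive of bin centers falling inside [lo, hi]
BANDS_NM = {
    "ghi": (200.0, 2700.0),
    "par": (400.0, 700.0),
    "uv": (280.0, 400.0),
    "uvb": (280.0, 315.0),
}

# total solar irradiance (W m-2) and solar effective temperature (K)
_TSI = 1361.0
_T_SUN = 5772.0

SPECTRAL_DEFAULTS = {
    "pressure_pa": 101325.0,
    "aod_500nm": 0.10,       # aerosol optical depth at 500 nm
    "angstrom_alpha": 1.14,  # Angstrom wavelength exponent
    "aerosol_ssa": 0.945,    # aerosol single-scattering albedo
    "aerosol_asym": 0.65,    # aerosol asymmetry parameter <cos theta>
    "overcast_transmission": 0.30,  # overcast-sky broadband transmission
}


@dataclass(frozen=True)
class SpectralGrid:
    """The fixed 200–2700 nm, 10 nm wavelength grid."""

    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS_NM.copy())

    @property
    def bin_width(self) -> float:
        return 10.0

    def band_slice(self, band: str) -> slice:
        try:
            lo, hi = BANDS_NM[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS_NM)}")
        idx = np.nonzero((self.wavelengths >= lo) & (self.wavelengths <= hi))[0]
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def band_weights(self, band: str) -> np.ndarray:
        """Per-bin integration widths (nm) for a band: the overlap of each
        10 nm bin [center-5, center+5] with the band's exact edges, so a
        flat 1 W m-2 nm-1 spectrum integrates to the band width."""
        try:
            lo, hi = BANDS_NM[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS_NM)}")
        half = self.bin_width / 2.0
        left = np.maximum(self.wavelengths - half, lo)
        right = np.minimum(self.wavelengths + half, hi)
        return np.clip(right - left, 0.0, None)


@dataclass
class SolarGeometry:
    """Solar position at one place and time.

    ``zenith_deg`` and ``distance_factor`` may be numpy arrays when computed
    for many cells at once; all downstream functions broadcast.
    """

    latitude: float
    longitude: float
    timestamp: pd.Timestamp
    zenith_deg: np.ndarray | float
    distance_factor: np.ndarray | float  # (mean distance / distance)^2

    @property
    def cos_zenith(self):
        return np.maximum(np.cos(np.deg2rad(self.zenith_deg)), 0.0)


@dataclass
class SpectralIrradiance:
    """Direct-normal and diffuse-horizontal spectra (W m-2 nm-1)."""

    grid: SpectralGrid
    dni: np.ndarray  # (..., n_wavelengths)
    dhi: np.ndarray
    cos_zenith: np.ndarray | float

    @property
    def ghi(self) -> np.ndarray:
        cz = np.asarray(self.cos_zenith)[..., np.newaxis] if np.ndim(self.cos_zenith) else self.cos_zenith
        return self.dni * cz + self.dhi

    def band_integral(self, band: str) -> np.ndarray:
        """Broadband irradiance (W m-2) of ``band`` from the GHI spectrum."""
        return (np.asarray(self.ghi) * self.grid.band_weights(band)).sum(axis=-1)

    def scaled(self, factor: float) -> "SpectralIrradiance":
        return SpectralIrradiance(self.grid, self.dni * factor, self.dhi * factor, self.cos_zenith)


@dataclass
class OzoneProfile:
    """Ozone volume-mixing-ratio profile on pressure levels.

    ``pressure_hpa`` strictly decreasing upward; ``vmr_ppm`` in parts per
    million by volume.
    """

    pressure_hpa: np.ndarray
    vmr_ppm: np.ndarray

    def __post_init__(self):
        self.pressure_hpa = np.asarray(self.pressure_hpa, dtype=float)
        self.vmr_ppm = np.asarray(self.vmr_ppm, dtype=float)
        if self.pressure_hpa.size < 2:
            raise ValueError("ozone profile needs at least 2 levels")
        if not np.all(np.diff(self.pressure_hpa) < 0):
            raise ValueError("pressure levels must decrease strictly upward")
        if np.any(self.vmr_ppm < 0):
            raise ValueError("ozone mixing ratios must be nonnegative")


# --------------------------------------------------------------------------
# solar position (NOAA almanac equations, accurate to ~0.01 deg)

def _julian_day(ts: pd.Timestamp) -> float:
    ts = pd.Timestamp(ts)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts.to_julian_date()


def sun_ephemeris(timestamp):
    """Solar declination (rad), equation of time (minutes), and earth–sun
    distance factor (mean/actual squared) for one UTC time."""
    jd = _julian_day(timestamp)
    jc = (jd - 2451545.0) / 36525.0

    l0 = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = np.deg2rad(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    c = (
        np.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m) * 0.000289
    )
    true_long = l0 + c
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))

    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(eps) * np.sin(app_long))

    y = np.tan(eps / 2.0) ** 2
    l0r = np.deg2rad(l0)
    eot_min = 4.0 * np.rad2deg(
        y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * ecc * ecc * np.sin(2 * m)
    )

    nu = m + np.deg2rad(c)
    r_au = 1.000001018 * (1.0 - ecc**2) / (1.0 + ecc * np.cos(nu))
    dist_factor = (1.0 / r_au) ** 2
    return float(decl), float(eot_min), float(dist_factor)


def zenith_from_hour_angle(lat_deg, decl_rad, hour_angle_deg):
    """Solar zenith (deg) from latitude, declination, and hour angle."""
    phi = np.deg2rad(np.asarray(lat_deg, dtype=float))
    h = np.deg2rad(np.asarray(hour_angle_deg, dtype=float))
    cos_z = np.sin(phi) * np.sin(decl_rad) + np.cos(phi) * np.cos(decl_rad) * np.cos(h)
    return np.rad2deg(np.arccos(np.clip(cos_z, -1.0, 1.0)))


def solar_position(lat, lon, timestamp) -> SolarGeometry:
    """Solar zenith angle and earth–sun distance factor.

    ``lat``/``lon`` may be scalars or broadcastable arrays (degrees north /
    degrees east); ``timestamp`` is a single UTC time.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    decl, eot_min, dist_factor = sun_ephemeris(timestamp)

    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    minutes_utc = ts.hour * 60.0 + ts.minute + ts.second / 60.0
    tst = np.mod(minutes_utc + eot_min + 4.0 * lon, 1440.0)
    hour_angle = tst / 4.0 - 180.0
    zenith = zenith_from_hour_angle(lat, decl, hour_angle)

    return SolarGeometry(
        latitude=float(np.mean(lat)),
        longitude=float(np.mean(lon)),
        timestamp=ts,
        zenith_deg=zenith if zenith.ndim else float(zenith),
        distance_factor=dist_factor,
    )


# --------------------------------------------------------------------------
# extraterrestrial spectrum and gas coefficients

def _planck_spectral(wl_nm: np.ndarray, temp: float) -> np.ndarray:
    """Planck spectral radiance shape, arbitrary units per nm."""
    wl_m = wl_nm * 1e-9
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    return wl_m**-5 / np.expm1(h * c / (wl_m * kb * temp))


def extraterrestrial_spectrum(grid: SpectralGrid | None = None) -> np.ndarray:
    """Top-of-atmosphere irradiance (W m-2 nm-1) at mean earth–sun distance.

    Planck spectrum at the solar effective temperature normalized so the full
    (0–inf) spectrum integrates to the total solar irradiance.
    """
    grid = grid or SpectralGrid()
    wl_fine = np.arange(10.0, 20000.0, 2.0)
    total = np.trapezoid(_planck_spectral(wl_fine, _T_SUN), wl_fine)
    return _TSI * _planck_spectral(grid.wavelengths, _T_SUN) / total


def _gauss(wl, center, width, amp):
    return amp * np.exp(-(((wl - center) / width) ** 2))


def ozone_absorption_coeff(wl_nm: np.ndarray) -> np.ndarray:
    """Ozone absorption coefficient, (atm-cm)^-1.

    Band model: Hartley band (peak ~255 nm), a Huggins shoulder, and the weak
    Chappuis band in the visible.  Magnitudes track published laboratory
    cross-sections to within the accuracy this parameterization aims for.
    """
    wl = np.asarray(wl_nm, dtype=float)
    a = (
        _gauss(wl, 255.0, 24.5, 300.0)
        + _gauss(wl, 310.0, 16.0, 1.5)
        + _gauss(wl, 600.0, 80.0, 0.12)
    )
    return a


def water_absorption_coeff(wl_nm: np.ndarray) -> np.ndarray:
    """Water-vapor absorption coefficient band model, cm^-1 (per cm of
    precipitable water), significant only in the near infrared."""
    wl = np.asarray(wl_nm, dtype=float)
    bands = [
        (720.0, 12.0, 0.15),
        (820.0, 14.0, 0.08),
        (940.0, 25.0, 1.6),
        (1130.0, 30.0, 2.6),
        (1380.0, 45.0, 28.0),
        (1870.0, 55.0, 180.0),
        (2700.0, 110.0, 450.0),
    ]
    a = np.zeros_like(wl)
    for center, width, amp in bands:
        a += _gauss(wl, center, width, amp)
    return a


# --------------------------------------------------------------------------
# airmass and transmittances

def relative_airmass(cos_z):
    """Kasten–Young relative airmass; large but finite near the horizon."""
    z = np.rad2deg(np.arccos(np.clip(cos_z, 0.0, 1.0)))
    return 1.0 / (np.clip(cos_z, 1e-4, None) + 0.50572 * (96.07995 - z) ** -1.6364)


def ozone_airmass(cos_z, layer_height_km: float = 22.0):
    h = layer_height_km / 6370.0
    return (1.0 + h) / np.sqrt(np.clip(cos_z, 0.0, 1.0) ** 2 + 2.0 * h)


def clearsky_spectral(
    geom: SolarGeometry,
    toz_du: float,
    prw_kgm2: float,
    grid: SpectralGrid | None = None,
    params: dict | None = None,
) -> SpectralIrradiance:
    """Clear-sky direct-normal and diffuse-horizontal spectra.

    Parameters
    ----------
    toz_du : total column ozone, Dobson units (> 0)
    prw_kgm2 : precipitable water, kg m-2 (1 kg m-2 == 1 mm == 0.1 cm)
    """
    if np.any(np.asarray(toz_du) <= 0):
        raise ValueError("total column ozone must be positive")
    if np.any(np.asarray(prw_kgm2) < 0):
        raise ValueError("precipitable water must be nonnegative")
    grid = grid or SpectralGrid()
    p = dict(SPECTRAL_DEFAULTS)
    if params:
        p.update(params)

    wl = grid.wavelengths
    wl_um = wl / 1000.0
    cos_z = np.atleast_1d(np.asarray(geom.cos_zenith, dtype=float))[..., np.newaxis]
    dist = np.atleast_1d(np.asarray(geom.distance_factor, dtype=float))[..., np.newaxis]
    toz = np.atleast_1d(np.asarray(toz_du, dtype=float))[..., np.newaxis]
    prw = np.atleast_1d(np.asarray(prw_kgm2, dtype=float))[..., np.newaxis]

    up = np.squeeze(cos_z, -1) > 0.0  # daylight mask

    et = extraterrestrial_spectrum(grid) * dist

    m = relative_airmass(np.squeeze(cos_z, -1))[..., np.newaxis]
    m_prime = m * p["pressure_pa"] / 101325.0
    m_o = ozone_airmass(np.squeeze(cos_z, -1))[..., np.newaxis]

    # Rayleigh
    t_r = np.exp(-m_prime / (wl_um**4 * (115.6406 - 1.335 / wl_um**2)))
    # aerosol
    tau_a = p["aod_500nm"] * (wl_um / 0.5) ** (-p["angstrom_alpha"])
    t_a = np.exp(-tau_a * m)
    # ozone (DU -> atm-cm)
    t_o = np.exp(-ozone_absorption_coeff(wl) * (toz / 1000.0) * m_o)
    # water vapor (kg m-2 -> cm of precipitable water)
    w_cm = prw / 10.0
    aw = water_absorption_coeff(wl)
    awm = np.clip(aw * w_cm * m, 0.0, None)
    t_w = np.exp(-0.2385 * awm / (1.0 + 20.07 * awm) ** 0.45)

    dni = et * t_r * t_a * t_o * t_w

    # diffuse: Rayleigh- and aerosol-scattered components
    omega = p["aerosol_ssa"]
    t_aa = np.exp(-(1.0 - omega) * tau_a * m)  # aerosol absorption only
    t_as = np.exp(-omega * tau_a * m)          # aerosol scattering only
    alg = np.log(1.0 - p["aerosol_asym"])
    afs = alg * (1.459 + alg * (0.1595 + 0.4129 * alg))
    bfs = alg * (0.0783 + alg * (-0.3824 - 0.5874 * alg))
    fs = 1.0 - 0.5 * np.exp((afs + bfs * cos_z) * cos_z)

    ray_term = et * cos_z * t_o * t_w * t_aa * (1.0 - t_r**0.95) * 0.5
    aer_term = et * cos_z * t_o * t_w * t_aa * t_r**1.5 * (1.0 - t_as) * fs
    # short-wavelength correction of the scattered spectrum
    cs = np.where(wl_um <= 0.45, (wl_um + 0.55) ** 1.8, 1.0)
    dhi = (ray_term + aer_term) * cs

    night = ~up[..., np.newaxis]
    dni = np.where(night, 0.0, dni)
    dhi = np.where(night, 0.0, dhi)

    scalar = np.ndim(geom.cos_zenith) == 0
    if scalar:
        dni, dhi = dni[0], dhi[0]
    return SpectralIrradiance(grid, dni, dhi, geom.cos_zenith)


# --------------------------------------------------------------------------
# clouds

def diffuse_fraction(clt, geom: SolarGeometry, tau: float = 0.70):
    """Fraction of global irradiance that is diffuse, after Campbell–Norman.

    Clear-sky beam transmittance tau^m and diffuse transmittance
    0.3 (1 - tau^m) give the clear-sky fraction; cloud cover interpolates
    linearly toward the fully diffuse overcast limit.
    """
    clt = np.asarray(clt, dtype=float)
    if np.any((clt < 0) | (clt > 1)):
        raise ValueError("cloud fraction must lie in [0, 1]")
    m = relative_airmass(np.asarray(geom.cos_zenith))
    tb = tau**m
    td = 0.3 * (1.0 - tb)
    rho_clear = td / np.clip(tb + td, 1e-12, None)
    return rho_clear * (1.0 - clt) + clt


def apply_cloud_opacity(
    clear: SpectralIrradiance,
    clt,
    geom: SolarGeometry,
    overcast_transmission: float | None = None,
) -> SpectralIrradiance:
    """Partly-cloudy spectra as a cloud-fraction-weighted average of the
    clear sky and an overcast sky.

    The overcast sky is entirely diffuse with the spectral shape of the
    clear-sky global irradiance scaled by the overcast transmission.
    """
    if overcast_transmission is None:
        overcast_transmission = SPECTRAL_DEFAULTS["overcast_transmission"]
    clt = np.asarray(clt, dtype=float)
    if np.any((clt < 0) | (clt > 1)):
        raise ValueError("cloud fraction must lie in [0, 1]")
    w = clt[..., np.newaxis] if clt.ndim else clt
    ghi_clear = clear.ghi
    dni = clear.dni * (1.0 - w)
    dhi = clear.dhi * (1.0 - w) + overcast_transmission * ghi_clear * w
    return SpectralIrradiance(clear.grid, dni, dhi, clear.cos_zenith)


# --------------------------------------------------------------------------
# ozone column from a mixing-ratio profile

#: DU per (ppm * hPa): 10 * R * T0 / (g0 * P0)
DOBSON_PER_PPM_HPA = 10.0 * 287.3 * 273.15 / (9.80665 * 1.01325e5)


def vmr_profile_to_dobson(profile: OzoneProfile) -> float:
    """Total column ozone (Dobson units) from a VMR profile.

    Trapezoidal sum over pressure layers:
    toz = 10 (R T0 / g0 P0) * sum_i 0.5 (VMR_i + VMR_{i+1}) (p_i - p_{i+1})
    with VMR in ppm and p in hPa.
    """
    vmr = profile.vmr_ppm
    p = profile.pressure_hpa
    layer_sum = float(np.sum(0.5 * (vmr[:-1] + vmr[1:]) * (p[:-1] - p[1:])))
    return DOBSON_PER_PPM_HPA * layer_sum
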