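# Methods

This note documents the model chain, the defaults that matter, the synthetic
forcing used for testing, and the design choices made where the design was
genuinely open.

## Clear-sky spectral irradiance

Direct-normal (DNI) and diffuse-horizontal (DHI) irradiance are computed on a
fixed 200–2700 nm grid at 10 nm resolution (251 bins) in the functional form
of the Bird simple spectral model: the extraterrestrial spectrum is
attenuated by multiplicative transmittances for Rayleigh scattering
(`exp(−M′/(λ⁴(115.6406 − 1.335/λ²)))`, λ in µm, pressure-scaled airmass M′),
aerosol extinction (Ångström law, defaults AOD₅₀₀ = 0.10, α = 1.14,
single-scattering albedo 0.945, asymmetry 0.65), ozone absorption
(`exp(−a_o(λ)·u·M_o)`, u in atm-cm from the `toz` forcing in DU), and water
vapor (`exp(−0.2385 aW M/(1+20.07 aW M)^0.45)`, precipitable water from
`prw`). The diffuse component carries the Rayleigh- and aerosol-scattered
terms with a forward-scatter fraction from the aerosol asymmetry parameter
and a short-wavelength correction `(λ+0.55)^1.8` below 450 nm.

Two coefficient sets are parameterized rather than tabulated: the
extraterrestrial spectrum is a Planck curve at the solar effective
temperature (5772 K) normalized to a total solar irradiance of 1361 W m⁻²,
and the ozone/water-vapor absorption coefficients are analytic band models
(Hartley/Huggins plus Chappuis for ozone; seven near-infrared Gaussian bands
for water vapor) with magnitudes tracking laboratory spectra. This keeps the
model self-contained and smooth on the 10 nm grid; it reproduces broadband
clear-sky GHI within the plausible midlatitude range (the suite checks
700–1100 W m⁻² at 30° zenith) and the correct ozone/water-vapor response
directions, but it is not a line-by-line code and individual 10 nm bins
should not be over-interpreted.

Solar position uses the NOAA almanac equations (declination, equation of
time, eccentricity), accurate to ~0.01°, with the earth–sun distance factor
applied to the extraterrestrial spectrum.

## Clouds

A partly cloudy sky is a cloud-fraction-weighted average of the clear sky
and an overcast sky. The overcast sky is entirely diffuse, with the spectral
shape of the clear-sky global irradiance scaled by an overcast transmission
of 0.30 (configurable). Consequences: zero cloud returns the clear sky
unchanged, full cloud extinguishes the direct beam, and broadband GHI
decreases strictly with cloud fraction. The Campbell–Norman construction
(beam transmittance 0.7^M, diffuse 0.3(1−0.7^M)) provides the standalone
diffuse-fraction diagnostic, interpolated linearly to 1 at full overcast.

## Bias correction

Global irradiance is scaled by 1.17 before albedo and attenuation (default,
configurable; 1.0 disables). This is the multiplicative correction that
aligns simple one-layer RTMs of this type with reanalysis shortwave at high
latitudes; it is applied uniformly in wavelength.

## Ocean surface albedo (OSA)

Open water reflects through four terms, all spectral:

- **Fresnel direct reflection** with a weakly dispersive refractive index
  (n ≈ 1.34), damped at grazing angles by wave roughness: the Cox–Munk
  mean-square slope σ² = 0.003 + 0.00512·u gives a damping factor
  `clip(1 − 2σ(θ/90°)³, 0.3, 1)`. Direct albedo remains nondecreasing in
  zenith angle; wind flattens the glint at high zenith.
- **Diffuse reflection**: the hemispherically averaged Fresnel reflectance
  (≈ 0.053–0.066) with a linear wind-slope reduction (factor 1 − 0.35σ).
- **Whitecaps**: coverage 3.97·10⁻⁴·u^1.59 with a flat 0.22 albedo.
- **Water-leaving reflectance**: 0.33·b_b/(a+b_b) through the interface,
  with pure-seawater absorption from a shipped table, pure-seawater
  backscatter `0.00144(500/λ)^4.32`, and chlorophyll adding pigment
  absorption (the shipped a*(λ) table times chl) and particulate backscatter
  `0.002·chl^0.62`. This gives blue, clear-water reflectance up to ~10 % at
  low chlorophyll and the expected color shift as chlorophyll rises.

Sensitivity toggles mirror the model-analysis switches: OSA vs a fixed 0.06
ocean albedo, wind on/off, chlorophyll-in-OSA on/off.

## Sea-ice, snow, and melt-pond albedo

Broadband constants in the CICE/CCSM heritage, applied flat across the
spectrum: thick bare ice 0.52 and snow-covered ice 0.65 (annual-average
values that already fold in seasonal surface deterioration; pure-ice 0.73
and pure-snow 0.96 are retained as metadata only). Ice thinner than 0.5 m
blends between the open-ocean albedo and 0.52 via
`f_h = min(atan(5h)/atan(2.5), 1)`.

**Melt ponds.** Ponds darken the surface: the albedo is reduced by up to
0.075, ramping linearly as near-surface air temperature rises from −1 °C to
0 °C. A literal reading of one common printed form of this correction
(`f_T = min(T_air − 1, 0)` subtracted) would *raise* albedo in the cold
limit, which contradicts both the physics of ponds and the documented
sensitivity direction (removing ponds reduces in-water PAR); the ramp
implemented here preserves the stated −1 °C onset and the CICE-style
magnitude while keeping the correct sign. The snow-covered-ice albedo also
receives the pond correction when warm (toggleable via
`AlbedoParams.pond_on_snow`).

Snow cover fraction (`sisnconc`) is interpreted as the snow-covered fraction
of the *ice-covered* area, so the cell albedo is
`(1−siconc)·OSA + siconc·[(1−sisnconc)·a_ice + sisnconc·a_snow]`.

## Attenuation

- **Snow**: `exp(−k_snow·h_snow)` at all wavelengths, k_snow = 20 m⁻¹
  (middle of the observed 4.3–40 m⁻¹ range; 5.9 m⁻¹ is the standard
  sensitivity alternative).
- **Sea ice**: `exp(−k(λ)·h_ice)` with a spectral coefficient table on
  200–1000 nm; wavelengths beyond 1000 nm transmit nothing under ice (the
  near infrared is strongly absorbed). The transmission direction is
  below-ice = top-of-ice × exp(−k h).
- **Chlorophyll**: Beer–Lambert with the chlorophyll-specific absorption
  spectrum a*(λ)·chl over a 0–5 m layer; the layer mean uses the analytic
  factor `(1−e^(−κz))/(κz)` per wavelength. The primary in-water output is
  the irradiance just below the interface (or ice underside); the 0–5 m
  chlorophyll-attenuated layer mean is the water-column metric used by the
  sensitivity analyses and the feeding-threshold metrics, since it is the
  quantity chlorophyll actually modulates.

**Shipped coefficient tables are constructed stand-ins.** The spectral ice
absorption, phytoplankton-specific absorption, and pure-water absorption
tables (`src/cryolight/data/*_synthetic.tsv`) carry representative
magnitudes and shapes, not digitized laboratory values; any user table in
the same two-column format can be substituted. Results that depend on exact
spectral detail (not on directions, bounds, or band-scale magnitudes) should
use replacement tables.

**Band integration** is a bin sum with each 10 nm bin weighted by its
overlap with the exact band edges (PAR 400–700, UV 280–400, UV-B 280–315,
GHI 200–2700 nm), so a flat spectrum integrates exactly to the band width.
PAR converts to photon flux with 4.57 µmol s⁻¹ W⁻¹ (the quantum factor
consistent with the 0.1 W m⁻² ↔ 0.457 µmol m⁻² s⁻¹ feeding-threshold pair).

## Engine

For the 15th of each month the chain is evaluated at six instants 4 h apart
in *local solar* time (hour angles −180°…+120°), so every longitude sees the
same diurnal sequence and cells are strictly independent; the monthly value
is the simple mean of the six instants, not a true monthly integral. The
anchoring is recorded in the output metadata. Cells with any missing forcing
are masked and reported, never filled. Runs are deterministic for a fixed
configuration.

## Total column ozone from mixing-ratio profiles

When a volume-mixing-ratio profile is supplied instead of the `toz` forcing,
the column is `10·(R·T₀/(g₀·P₀)) · Σ 0.5(VMR_i+VMR_{i+1})(p_i−p_{i+1})`
with R = 287.3 J kg⁻¹ K⁻¹, T₀ = 273.15 K, g₀ = 9.80665 m s⁻², P₀ =
1.01325·10⁵ Pa, VMR in ppm and p in hPa — 0.78977 DU per (ppm·hPa), linear
in VMR. The UV response to ozone is realized entirely through the spectral
ozone transmittance, not by a separate post-hoc scaling.

## Ensemble weighting

Models are scored on sea-surface-temperature diagnostics over 66–80°N:
per-cell climatology, linear trend, and detrended interannual standard
deviation. The trend is fitted to *annual means* so the seasonal cycle
cannot leak into the slope (monthly regression of an annual harmonic has an
intrinsic within-year covariance with time). Distances are area-weighted
RMSEs per diagnostic, each normalized by the ensemble median of that
diagnostic's distance-to-observations, then averaged across the three
diagnostics — the equal-weight normalized mean is a choice, exposed in the
code, since no canonical combination exists. Realizations of one model are
averaged before distances. Raw weights follow
`exp(−D²/σ_D²)/(1+Σ_{j≠i}exp(−S_ij²/σ_S²))` and are normalized to sum to 1
(the raw form is unnormalized; averaging needs a partition of unity).
σ_D and σ_S default to the ensemble medians of D and off-diagonal S; both
are overridable. A pseudo-observation mode (a perturbed generator run) makes
the pipeline testable without observational archives.

## Regional metrics

The two ecosystems are shipped as approximate lon/lat boxes
(Northern Bering–Chukchi: 62–75°N, 178–205°E, center 69.5°N; Barents:
68–80°N, 20–55°E, center 75.0°N); exact ecosystem polygons can be supplied
as boolean masks. Open water is `siconc < 0.15` (community convention).
Months-above-threshold per half-year (Jan–Jun / Jul–Dec) is the length of
time the piecewise-linear interpolant through month-center values exceeds
the threshold, with a flat half-month at each end of the window — six
qualifying months give exactly 6.0 and a crossing contributes the
interpolated fraction of its interval. Decadal anomaly tables subtract the
1980–2000 monthly climatology from each decade's monthly means.

## Fish thermal responses

Each species/stage curve is a scaled beta over its thermal window
`[T_low, T_high]`: `f(T) = peak·x^p·y^q` with `x, y` the normalized
distances from the limits and exponents proportional to `(T_opt−T_low)` and
`(T_high−T_opt)` (overall steepness 2.5), so the maximum is exactly
`(T_opt, peak)`, the curve is zero at and beyond both limits, and it is
continuous there. Optima and peaks: Atlantic cod egg (4.3 °C, 93 %),
juvenile (14 °C, 4.7 %/d); polar cod egg (0.2 °C, 88 %), juvenile (7.5 °C,
1.5 %/d); walleye pollock egg (3.6 °C, 83 %), juvenile (13 °C, 3.0 %/d).
Polar cod limits are laboratory-reported (egg upper 4.5 °C; juvenile window
−1…12 °C); the polar cod egg lower limit is set at −2 °C (near seawater
freezing), and the remaining windows default to literature-typical ranges —
all limits and the steepness are configurable, so digitized curves can be
substituted. Egg metrics use February–April temperatures and juvenile
metrics May–July by default (a January–March winter window is also in use in
the literature; the months are a parameter). Light is deliberately not an
input to the biology: light-threshold feeding metrics live in the regional
module, and the biology sees light only through its effect on temperature.

## Synthetic forcing

The generator emulates the statistical structure of polar monthly forcing:
latitude-dependent seasonal cycles for all twelve variables (winter sea-ice
maximum in March, minimum in September; summer air/ocean temperature peaks;
a spring chlorophyll bloom near May–June whose peak advances by a
configurable 3 days per decade), scenario-dependent linear trends per
century (e.g. tas +3 / +6 °C, siconc −0.35 / −0.60, toz +20 / +50 DU for
the intermediate / high scenarios), bounded fractions with clamping (logged
when trends push them out of range), ~82 % mean cloud cover, and optional
white noise. It is deterministic per seed. It does **not** emulate spatial
weather patterns, interannual modes, ice dynamics, or model-to-model
structural differences — so passing tests demonstrate the correctness and
directional behavior of the transfer chain, not the realism of any
particular climate trajectory; headline magnitudes from real CMIP6 forcing
are out of reach of the synthetic harness by design.

## Problem sizes and numerics

The test and acceptance runs use a coarsened domain (latitudes 61–82° in 3°
steps, longitudes 0–330° in 30° steps, 96 cells) over two- and ten-year
spans, chosen so the full directional-sensitivity suite (five full RTM runs)
completes in well under a minute while still spanning ice-covered, marginal,
and open-water regimes across the seasonal cycle. Degenerate inputs are
handled explicitly: polar night yields exactly zero light; zero thicknesses
yield unit transmittance; zero chlorophyll is the identity; masked forcing
yields masked output. Night masking, clamped fractions, and the arctangent
blend make all per-cell operations continuous in their inputs. Monthly
timestamps sit on the 15th of each month everywhere.

## Known limitations

One-dimensional, single-layer atmosphere; no cloud layering or land
reflection; no soot or ice-algae darkening (ice and snow are treated as
pure); no cDOM or non-algal particle attenuation; in-water light stops at
the 0–5 m layer (no full water-column profiles); the biology is a static
thermal response without bioenergetics, prey coupling, or movement. The
spectral coefficient stand-ins are the main accuracy limitation for
wavelength-resolved results.
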