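# Methods

`habwatch` implements a desk-scale harmful-algal-bloom (HAB) monitoring
pipeline for optically complex inland waters such as Lake Victoria's Winam
Gulf: two satellite proxies of bloom activity — chlorophyll-a concentration
and lake surface air temperature (LSAT) — retrieved per pixel from
Landsat-8-style scenes, a paired-raster validation workflow, a synthetic
scene generator that makes every stage testable against known truth, and a
threshold alerting engine modelled on an in-situ IoT sensor station.

## Chlorophyll-a: the OC-2 band-ratio model

Chlorophyll-a (mg/m³) is the universal optical proxy for algal biomass. The
OC-2 algorithm is an empirical two-band ocean-color model:

    Chl-a = 10^(a0 + a1·R + a2·R² + a3·R³ + a4·R⁴),
    R     = log10(Rrs(490) / Rrs(555)),

with default coefficients (0.2511, −2.0853, 1.5035, −3.1747, 0.3383). The
scene's blue band (~482 nm) stands in for Rrs(490) and the green band
(~560 nm) for Rrs(555); Level-2 surface reflectance is fed in directly as
Rrs (a scalar pre-factor is exposed for sensitivity studies; as a common
factor it cancels in the ratio). On R ∈ [−1, 1] the polynomial exponent is
strictly decreasing (verified on a dense grid), so the model is monotone:
greener water means more chlorophyll. Being a power of ten the output is
strictly positive; reported negative "chlorophyll" values in some published
tables cannot arise from this model and are not emulated.

Quantized reflectance counts are rescaled as `dn × scale + offset`
(defaults: 2.75e-5 and −0.2, the Collection-2 Level-2 convention). Pixels
whose reflectance comes out non-positive are masked invalid, never clipped:
the log-ratio is undefined there and clipping would fabricate blooms.

## LSAT: the mono-window (single-channel) chain

Band-10 counts are converted to at-sensor radiance `Lλ = ML·QCal + A_L`
(defaults ML = 0.0003342, A_L = 0.1), then to brightness temperature by the
Planck-form inversion `Tb = K2 / ln(K1/Lλ + 1) − 273.15` (°C). K1/K2
default to the standard published band-10 constants (774.8853,
1321.0789 K) — these are *not* scene-specific and should be overridden from
the product metadata when available.

Emissivity comes from NDVI = (NIR − RED)/(NIR + RED) through the
proportional-vegetation fraction `Pv = ((NDVI − NDVImin)/(NDVImax −
NDVImin))²` and `ε = 0.004·Pv + 0.986` (so ε ∈ [0.986, 0.990]). NDVImin/max
default to the per-scene extremes over valid AOI pixels; fixed values can
be supplied for cross-scene reproducibility. Pv is clamped to [0, 1] after
squaring so fixed stats tighter than the scene's range cannot push it out
of bounds; a degenerate range (max = min, e.g. open water with uniform
NDVI) yields Pv = 0.

The mono-window correction is

    LSAT = Tb10 / (1 + (λ·Tb10/ρ)·ln ε),

with λ = 10.895 µm (band-10 effective wavelength) and ρ = h·c/σ =
1.4388×10⁻² m·K. Two unit modes are provided because mono-window workflows
in the applied literature differ on whether Tb enters the correction in °C
or K. The default `celsius` mode uses Tb in °C throughout; the `kelvin`
mode applies the correction on the Kelvin scale and converts back. At lake
temperatures (ε ≈ 0.986, Tb ≈ 30 °C) the correction is ~0.01 °C in Celsius
mode and ~1 °C in Kelvin mode; the package surfaces the difference rather
than silently choosing, and the synthetic generator encodes with the
Celsius convention so round trips are self-consistent.

## Validation

The reference raster (typically a coarser product, e.g. 300 m or 1 km) is
resampled to the estimate grid by nearest neighbour; 500–1000 jointly valid
pixels are drawn uniformly without replacement with an explicit seed
(requests beyond availability are clipped and logged). Raw values are
compared, never normalized. Metrics: MSE, RMSE, MAE, and R² reported as the
squared Pearson correlation — the quantity that belongs next to a fitted
regression line on a scatter plot — together with the OLS slope/intercept
of estimate on reference. The identity-line variant 1 − SSres/SStot is also
computed (`r2_identity`) for users who need agreement rather than
association. A zero-variance reference leaves R² undefined (NaN) while the
error metrics stay finite. MAE ≤ RMSE always (power-mean inequality), and
RMSE² = MSE by construction.

## Synthetic scenes

The generator encodes known truth through the inverse of the retrieval
equations, so the full chain is testable without downloads.

* **Truth fields.** Chl-a = background + isotropic Gaussian bumps
  (peak − background)·exp(−d²/2r²); blooms in imagery appear as compact
  hotspots, and a Gaussian is the simplest shape with a controllable peak
  and background. LSAT = background + coupling·(Chl-a − background): warm
  spots co-locate with blooms, and an affine link keeps the truth
  invertible and the coupling interpretable (default 0.2 °C per mg/m³).
  No empirically established joint functional form exists; the slope is a
  free scenario parameter.
* **Presets "2015"–"2020"** pin background/peak Chl-a (1.2–57.1 mg/m³) and
  background LSAT (16.9–28.7 °C) to the extremes observed in the
  corresponding Winam Gulf bloom years. The 2016 background uses the
  magnitude 1.2 mg/m³ (the reported negative low is unreachable by the
  model). Default grid 64×64 at 30 m.
* **Encoding.** Green reflectance is held at a water-like baseline
  (default 0.05 — high enough that the ±½-count quantization error stays
  well under the 2% round-trip budget); blue = green·10^R with R from a
  bracketed root-find of the OC-2 polynomial (unique on R ∈ [−0.8, 0.6]
  for Chl-a ∈ [0.5, 60] mg/m³, solved to ~1e-13 in the exponent). Red/NIR
  are water-typical constants (0.02/0.01), giving one fixed NDVI whose Pv
  under the scenario's declared stats yields the encoding emissivity. The
  thermal path inverts the mono-window correction in closed form and the
  Planck relation to a 16-bit count. Gaussian noise, when requested, is
  added in physical units (reflectance / °C) *before* quantization,
  mimicking residuals acting upstream of the integer product. Default
  noise levels of 0.0005 reflectance and 0.5 °C reproduce the
  strong-agreement validation regime (R² > 0.8); the in-situ sensor
  emulation assumes a DHT11-class envelope of 0–50 °C at ±2 °C.
* **What it does not emulate.** Radiative-transfer effects, clouds,
  spatially correlated atmospheric error, inter-band spectral correlation
  beyond the OC-2 relation, or adjacency effects. Passing round-trip tests
  therefore demonstrates correctness of the *computational chain* and its
  quantization behaviour, not retrieval skill on real imagery.
* **Degraded references** for exercising the validation module are
  block-mean coarsenings of truth plus bias and seeded noise; they are
  synthetic stand-ins, not re-creations of any external product.

Everything is a pure function of (scenario, seed): identical inputs yield
bit-identical scenes.

## Alerting

Sensor readings (station id, GMT timestamp, WGS84 position, temperature)
are screened against a threshold; the usual bloom-alert band is
26–35.1 °C and values outside it only warn. "Exceeds" is strict
inequality, making the threshold itself a safe non-alert value. At most
one alert per station per GMT calendar day by default (GMT because that is
the timestamp convention of the emulated logger). Readings outside the
sensor's trusted 0–50 °C envelope are flagged and excluded, not clamped.
Messages embed the LSAT to 2 decimals, the GMT time, and a
`maps.google.com/?q=lat,lon` link with 5-decimal coordinates. The SMS
transport is a pluggable sink (in-memory and JSON-lines file
implementations); delivery failures are retried a configurable number of
times and then logged undelivered, so emitted = delivered + undelivered
always. NMEA GGA sentences are parsed with XOR-checksum verification and
ddmm.mmmm → signed decimal degree conversion.

## Numerical and I/O choices

* GeoTIFF I/O is implemented over `tifffile` with the standard
  ModelPixelScale/ModelTiepoint/GDAL_NODATA tags (north-up transforms
  only; no reprojection). Fields are stored as float64 with NaN nodata, so
  write→read round trips are bit-exact. AOI polygons are GeoJSON.
* Pixel convention: 0-based row/col, pixel value located at the center,
  north-up affine. Point-in-polygon AOI tests use pixel centers.
* Test and round-trip problem sizes are 16–64 pixel grids with 500–1000
  validation samples — chosen because every numerical claim made here
  (quantization bounds, noise recovery, R² regime) is already resolvable
  at that scale.

## Known limitations

* Only the two-band OC-2 model is implemented (no OC-3/OC-4, turbidity or
  phycocyanin); empirical ocean-color polynomials are regionally tuned and
  the default coefficients may bias absolute Chl-a in other lakes.
* The mono-window chain assumes atmospherically corrected Level-2 inputs;
  no water-vapor modelling, no split-window (band 11) option.
* Emissivity is an NDVI proxy with a narrow [0.986, 0.990] range — adequate
  over water, crude over mixed shoreline pixels.
* The affine Chl-a→LSAT coupling in the generator is a modelling
  convenience, not an ecological claim.
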