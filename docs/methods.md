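# Methods

## Model structure and assumptions

The simulator represents one vine as a set of observed organ trajectories
(leaf area, shoot surface, cluster mass, light interception) driving a
daily source–sink carbon budget. It is an *observation-driven* model: the
canopy is not grown mechanistically, weekly field measurements are
interpolated to daily values and the model only computes the carbon
consequences. Carbon is not partitioned among organs and there are no
reserve (starch) dynamics; the output is whole-vine net dry matter.

### Photosynthesis

Leaf assimilation is a rectangular hyperbola in absorbed irradiance with
initial slope α (quantum yield, µg CO₂ J⁻¹) and asymptote Pₙmax
(g CO₂ m⁻² s⁻¹). Within the canopy, irradiance decays as I·e^(−K·ℓ) down
cumulative leaf area ℓ (Beer–Lambert, extinction coefficient K), and the
absorbed flux per unit leaf area at depth ℓ is K·I·e^(−K·ℓ). Integrating
the hyperbola over depth gives the closed form used by
`canopy_instantaneous`; the derivative of that closed form with respect to
canopy depth is exactly the leaf response at the attenuated flux, which is
what the layered-canopy oracle in the tests verifies numerically.

The canopy depth is not taken from measured leaf area but inverted from
the measured light-interception fraction, L = −ln(1−LI)/K. This honours
the ceptometer measurement as the authoritative description of how much
light the canopy actually captures — trellis geometry, row orientation and
gaps are all folded into LI — while K only shapes the within-canopy
gradient. A consequence worth knowing: lateral leaf area is carried as
data but has no separate photosynthetic pathway, so canopies with a large
lateral share are under-credited. This reproduces the characteristic
underestimation of dry matter in vertical-shoot-positioned canopies, which
carry more laterals.

Sub-daily integration uses a half-sine irradiance profile over the
geometric day length. The half-sine is the simplest shape that conserves
the measured daily total exactly (to quadrature error < 0.1% at the
default 48 steps); the daily assimilation total is far more sensitive to
the daily radiation integral than to the profile shape. Day length is
geometric sunrise-to-sunset (Cooper declination, hour-angle relation),
with no refraction or twilight; latitudes beyond ±66° are rejected.

A temperature factor multiplies the whole day's assimilation: inverted
parabolas on each side of the optimum, 0 at t_base and t_ceiling, 1 at
t_opt, evaluated at the daily mean (tmin+tmax)/2 since no sub-daily
temperatures exist. Defaults t_base 10 °C, t_opt 27.5 °C, t_ceiling 45 °C
bracket the thermal envelope of field photosynthesis in warm-climate
grapevine; all three are configurable.

### Respiration

Maintenance respiration of the shoot-surface pool (r20_shoot,
g CO₂ m⁻² day⁻¹) and the cluster pool (r20_cluster, g CO₂ g⁻¹ FW day⁻¹)
scales with the Arrhenius factor exp[(Eₐ/R)(1/293.15 − 1/T)]. The default
activation energy Eₐ = 51,200 J mol⁻¹ gives Q₁₀ = 2.00 between 20 and
30 °C, the canonical doubling. Day and night are treated separately —
T_day = (tmax+tmean)/2, T_night = (tmin+tmean)/2 — weighted by the
day-length fraction of 24 h. Growth respiration is a fixed charge
(growth_coeff, g CO₂ per m² of new leaf area) independent of temperature:
the construction cost of tissue is set by its composition, not by the
temperature at which it is built. Root and trunk respiration are not
modelled (they are not inputs of the system being emulated), so absolute
dry-matter totals should be read as shoot-system net carbon, and the
reference rates are calibration targets rather than literature constants.

### Carbon balance

dm_daily = (P − R) · f with f = 30/44 (g carbohydrate per g CO₂, CH₂O
stoichiometry, configurable). Negative daily balances are allowed and
accumulate; early-season respiration routinely exceeds photosynthesis
before the canopy develops. dm_cumulative is the exact running sum of
dm_daily — conservation is enforced by construction, not approximation.

### Calibration

`calibrate_scale` fits one multiplicative factor on Pₙmax (bounds
[0.1, 10], additionally clipped so the scaled Pₙmax stays inside its
physical ceiling of 0.005 g m⁻² s⁻¹) by bounded 1-D minimisation
(`scipy.optimize.minimize_scalar`, method `bounded`) of the sum of squared
**relative** residuals against measured cumulative dry matter. Relative
residuals are the maximum-likelihood weighting when sampling error scales
with the measured value (constant coefficient of variation), which is how
replicated destructive dry-matter samples behave and how the synthetic
generator draws its noise; an absolute-residual objective would be
dominated by the late-season points and, at the default study conditions,
roughly triples the dispersion of the recovered factor. Note that the
canopy is substantially light-limited at realistic parameter values, so
the elasticity of seasonal dry matter with respect to the Pₙmax scale is
only ≈ 0.3: a 5% observation error maps to roughly a 15% single-point
scale error, and precision comes from averaging over the sampling dates.

### Sugar regression and thinning scenarios

°Brix observations (between veraison and harvest) regress on simulated
cumulative dry matter by OLS; r² is the squared Pearson correlation. The
regressor is whole-vine cumulative dry matter, not per-cluster mass.
Scenario runs override clusters-per-vine for the whole season and
re-simulate; the cluster count affects the prediction only through cluster
maintenance respiration, so predicted Brix is pointwise non-increasing in
cluster count whenever r20_cluster > 0 and the fitted slope is positive.
Per-berry sugar dilution with larger crops is *not* modelled — the
scenarios isolate the carbon-budget pathway and should be read as such, a
known limitation.

## Goodness of fit

`evaluate` reports r² (squared Pearson), MAE, RRMSE = RMSE/mean(O) and
PBIAS = 100·Σ(O−P)/ΣO. The PBIAS sign convention is chosen so that a model
that underestimates the observations reports a **positive** bias;
published tables sometimes print magnitudes only, so the sign is stated
prominently in the report dataclass.

## Synthetic study conditions

The generator emulates a temperate mid-latitude (default 43.668° N)
April–September season of 165 days:

| parameter | default | rationale |
|---|---|---|
| Tmean seasonal curve | 18.5 − 6.5·cos(2π(doy−15)/365) °C | ≈12–25 °C April→July means |
| AR(1) deviations | sd 2 °C, φ 0.7 | synoptic-scale persistence |
| diurnal range | 7 + 6·(clear-sky fraction) °C | clearer days span wider |
| clear-sky fraction | 1 − 0.85·Beta(1.2, 3.5) | mostly clear, bounded below at 0.15 |
| radiation | 0.75 · extraterrestrial · clear fraction | 0.75 = clear-sky transmissivity |
| canopy growth | logistic, midpoint 45 DAS, scale 12 d | flattens at trimming (86 DAS) |
| cluster growth | double sigmoid (55 and 110 DAS) | lag phase around veraison |
| trellis profiles | VSP-like: LA 3.6 m², LI 0.16, 250 g, 10.2 clusters; SHW-like: 4.0 m², 0.18, 300 g, 9.2 | the two systems differ exactly where measured |
| dm noise | 5% multiplicative | destructive-sampling CV |
| Brix noise | 0.4 °Brix additive | refractometer + berry heterogeneity |
| true Brix law | 9 + 0.013·DM °Brix | ≈23 °Brix at the ~1 kg seasonal DM |

One `numpy.random.Generator` seeded from `SyntheticConfig.seed` threads
through weather, canopy and observations, so a season is byte-reproducible.

What the generator does **not** emulate: real weather sequences (fronts,
heat waves with radiation anomalies), water stress and its coupling to
photosynthesis, year-to-year canopy variation beyond a single lognormal
size factor, berry-level variance structure, or measurement error in the
canopy descriptions themselves. Passing tests on synthetic seasons
demonstrate the pipeline's internal consistency and parameter
recoverability under the assumed error structure — not field validity.

## Numerical choices

- Sub-daily integration: trapezoid over 48 half-sine steps; halving the
  step changes daily totals by < 0.2%.
- The canopy closed form is exact; the 1,000-layer midpoint oracle agrees
  to < 0.5% (the residual is the oracle's discretisation, not the form's).
- Calibration: bounded scalar minimisation, xatol 1e-5.
- Interpolation edge rules: organ sizes ramp linearly from zero at DAS 0
  before the first observation and hold constant after the last; cluster
  counts are stepwise at the nearest prior observation (counts do not
  interpolate); leaf-area increments clamp at zero so measurement dips do
  not produce negative growth respiration.
- Degenerate inputs are errors, not silent defaults: LI = 1, zero-variance
  observations in r², zero observed mean in RRMSE/PBIAS, weather/canopy
  day-coverage mismatches.
- Problem sizes in tests and the acceptance script (150–165-day seasons,
  48 sub-daily steps, 50-seed replicate batches) keep every stage
  comfortably sub-minute while leaving the statistics stable.

## Known limitations

Lateral leaves do not photosynthesise (see above); roots and trunk do not
respire; cluster-thinning scenarios ignore per-berry dilution; the Brix
model is linear (no double-sigmoid ripening kinetics); weather ingestion
is daily only, with no soil-water balance. The vein-length allometry
coefficient for estimating leaf area from main-vein lengths is
cultivar-specific and must be supplied by the user.
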