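# vitisim

Daily carbon-balance simulation of grapevine (*Vitis vinifera*) dry-matter
accumulation and berry sugar content, for comparing canopy-management
choices — trellis system, cluster thinning — over a growing season.

The model is aimed at viticulture researchers and decision-support work: it
consumes only routine field inputs (a daily weather table and weekly vine
descriptions) and produces the seasonal dry-matter trajectory, model
goodness-of-fit against measured dry matter, a °Brix-on-dry-matter
regression, and predicted sugar trajectories under alternative
clusters-per-vine counts.

## The model

Two sub-modules run at a daily time step, per vine:

**Photosynthesis.** The leaf light response is a rectangular hyperbola with
quantum yield α (µg CO₂ J⁻¹) saturating at *P*ₙ max (g CO₂ m⁻² s⁻¹).
Irradiance attenuates down the canopy following Beer–Lambert with
extinction coefficient *K*; the effective leaf-area index is inverted from
the measured light-interception fraction, *L* = −ln(1 − LI)/*K*. The canopy
integral has the closed form

```
Pc(I) = (Pmax/K) · ln[(α′KI + Pmax) / (α′KI·e^(−KL) + Pmax)]
```

per m² ground. Daily gross photosynthesis integrates *P*c over a half-sine
irradiance profile spanning the (geometric) day length, scaled by the
ground area per vine and a piecewise-quadratic temperature factor on the
daily mean temperature.

**Respiration.** Shoot surface (m²) and cluster fresh mass (g × clusters
per vine) respire at reference rates at 20 °C scaled by the Arrhenius
factor exp[(Eₐ/R)(1/293.15 − 1/T)], evaluated at day and night
temperatures weighted by day-length fraction; newly grown leaf area incurs
a temperature-independent growth-respiration charge.

The daily CO₂ balance (photosynthesis − respiration) converts to dry
matter with the CH₂O stoichiometric factor 30/44 and accumulates over the
season. Measured °Brix regresses linearly on simulated cumulative dry
matter (OLS); the fitted line predicts sugar trajectories when the season
is re-simulated with overridden cluster counts.

Because no field dataset is distributed, a seeded synthetic-season
generator (`vitisim.synthetic`) provides weather, canopy trajectories and
noisy observations with the structure the analysis assumes, including
VSP-like and SHW-like trellis profiles.

## Worked example

Generate a synthetic vertical-shoot-positioned season and run the pipeline:

```
$ vitisim synth --profile vsp --seed 42 --out demo/data
$ vitisim simulate --weather demo/data/weather.csv --canopy demo/data/canopy.csv --out demo/sim.csv
simulated 165 days; final dry matter 1073.8 g/vine
$ vitisim fit-sugar --brix demo/data/brix_obs.csv --results demo/sim.csv --out demo/fit.csv
slope 0.01256 °Brix/g  intercept 9.56  r2 0.937  n 10
$ vitisim evaluate --observed demo/data/dm_obs.csv --predicted demo/sim.csv
R2    0.9964
MAE   24.2926
RRMSE 0.0747
PBIAS +2.90%
$ vitisim scenario --weather demo/data/weather.csv --canopy demo/data/canopy.csv \
    --fit demo/fit.csv --clusters 6,12 --out demo/scen.csv
```

The vine fixes ≈1.07 kg of dry matter over the 165-day season. The ten
post-veraison refractometer readings regress on simulated dry matter with
r² = 0.937 — sugar accumulation tracks the simulated carbon gain. Against
the eight dry-matter samples the simulation shows a 2.9% positive bias
(slight underestimation) and an RRMSE of 7.5% of the observed mean. In the
thinning scenario, the 6-cluster season ends at 23.9 °Brix versus 22.7
°Brix with 12 clusters: fewer clusters mean less maintenance respiration,
more accumulated dry matter and a higher predicted sugar content.

`vitisim run-all --config run.yaml --out results/` chains every stage from
one YAML configuration; all outputs embed a digest of the resolved
configuration and re-runs are byte-identical.

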