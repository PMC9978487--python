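# bacclim

Box-model emulation, scenario synthesis and attribution of marine
heterotrophic bacterial carbon dynamics under climate-change scenarios.

The package provides:

- **`bacclim.model_core`** — a per-cell bacterial carbon box model: one
  biomass pool partitioned linearly between free-living (DOC-feeding) and
  particle-attached (POC-feeding) cells; cubic-Monod DOC uptake, Contois POC
  uptake with Martin-like depth attenuation, Q10 temperature scaling,
  basal + activity respiration with an oxygen regulating factor, type-2
  microzooplankton grazing and temperature-dependent mortality. Explicit
  Euler time stepping plus a fast vectorized steady-state solver.
- **`bacclim.scenario_synth`** — a seeded generator of gridded
  (year x depth x lat x lon) forcing fields carrying prescribed regional
  baselines and linear trends toward per-scenario end-century targets
  (ssp126/ssp245/ssp370/ssp585/historical), with smooth spatial anomalies and
  AR(1) interannual noise; synthetic station and gridded observations of
  bacterial abundance and thymidine incorporation with lognormal error and
  seeded gaps.
- **`bacclim.composites`** — trapezoidal depth integration (0–107 m) and
  averaging (10–107 m), latitudinal-band regionalization (NH/NI/LL/SI/SO),
  cos-latitude area-weighted composites with spatial standard errors, and
  baseline-vs-end-century change metrics.
- **`bacclim.attribution`** — exact first-order Taylor decomposition of
  changes in the free-living specific DOC uptake rate into DOC-control and
  temperature-control terms plus the cross-term residual; Arrhenius
  regression of production on inverse absolute temperature.
- **`bacclim.skill_eval`** — cell-abundance and thymidine unit conversions
  (with conversion-factor sensitivity), model–observation pairing, and skill
  scores: bias, average absolute error, RMSD with its exact
  bias/centered-RMSD decomposition, Pearson correlation and a multiplicative
  reliability index.
- **`bacclim.io_cli`** — packaged fixtures of the published composite tables,
  CF-style NetCDF round-tripping, YAML configuration, the end-to-end pipeline
  and the command-line interface.

## Command-line interface

```sh
bacclim generate --scenario ssp585 --seed 1 --grid 18x36 --years 1990:2099 --out fields.nc
bacclim simulate --forcing fields.nc --mode to_steady
bacclim composite --forcing fields.nc --variable DOC --out composites.csv
bacclim attribute --forcing fields.nc --out attribution.csv
bacclim skill --model fields.nc --obs obs.csv --mode monthly
bacclim fixtures table1
bacclim run --seed 1 --out results/
```

`bacclim run` executes the full chain: field generation, per-cell-year
quasi-steady biomass simulation, depth reduction, regional composites and
change metrics, Taylor attribution, and skill scoring against synthetic
observations, writing `composites.csv`, `attribution.csv`, `changes.csv`,
`skill.json` and the resolved `config.yaml`. Identical seeds give
byte-identical outputs.

Note on the quasi-steady default: with one-way forcing (bacteria do not
deplete the substrate pools) and the default parameters, cells with abundant
DOC have no finite steady state — free-living growth is linear in biomass and
exceeds all sinks. Such cell-years are pinned at the configured biomass cap
and counted in the log. Set `biomass_mode: prescribed` in the config to carry
the generated biomass fields instead and only diagnose process rates.

## Units

Concentrations are mmol C m⁻³ (oxygen: mmol O₂ m⁻³), rates mmol C m⁻³ d⁻¹,
depth-integrated stocks mmol C m⁻² over the upper 107 m, temperature °C.
Regional specs prescribe column stocks; the generator divides by the
shape-weighted layer thickness so that depth-integrated composites recover
the prescribed values exactly.
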