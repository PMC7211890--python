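# billclim

Pipeline for studying how a thermoregulatory trait — songbird **bill
surface area** (SA, mm²) — relates to **short-term relative temperature
extremity (RTE)** in interaction with the prevailing temperature and
precipitation regime, using historical museum-specimen data and monthly
gridded climate.

The package is aimed at researchers in ecomorphology / historical
ecology who want a tested, reusable implementation of this analysis:
the RTE statistic, point-buffer climate covariate construction, a
REML-fit generalized additive mixed model (GAMM) with a spatial smooth
and a year random intercept, its diagnostics, and a synthetic-data
generator that makes the whole chain testable end-to-end with a known
ground truth (the original specimen measurements and climate rasters
are not redistributable).

## The statistic and the model

For a specimen collected in year *t* at a locality, monthly climate is
averaged over grid cells whose centers lie within a 15 km great-circle
radius. For the summer months (April–August) of the five calendar years
before collection, the **relative minimum temperature** is

```
RTE_min = ( T̄min,1 − (1/5) Σᵢ T̄min,i ) / σ( T̄min,1..5 )
```

where T̄min,i is the mean monthly minimum summer temperature *i* years
prior, and σ is the sample standard deviation over the five yearly
summer means. RTE_max is defined likewise with maximum temperature.
The statistic is dimensionless and invariant to shifting or rescaling
temperature, so it is comparable across climates: large positive values
mean the prior summer was unusually warm *for that place*, large
negative values unusually cool.

Bill surface area is approximated from bill length *l*, width *w* and
depth *d* by a cone lateral surface, SA = π·r·√(r² + l²) with
r = (w + d)/4, and modelled as

```
SA = β₀ + β·[RTE_min, RTE_max, T̄, RTE×T̄, σ_T, P, RTE×P, month,
             subspecies, tarsus, sex]  +  f(lat, lon)  +  u_year  +  ε
```

where T̄ and σ_T are the 5-year summer mean temperature and its SD, P is
the prior summer's mean monthly precipitation, *f* is a thin-plate
regression spline of latitude/longitude (spatial autocorrelation
control), and u_year is a year random intercept. All variance and
smoothing components are estimated jointly by REML. Reported
diagnostics: Wald *t*/F tests, smooth effective degrees of freedom,
year/residual variance components, marginal and conditional R² for
mixed models, Moran's I on residuals, and generalized VIFs.

## Worked example

Simulate a full-size synthetic study (516 specimens, 1900–1950, a
PRISM-like 0.04° monthly climate grid) whose generative coefficients
are the published estimates, then refit:

```python
import warnings
from billclim import synthetic_data as sd, gamm

params = sd.GenerativeParams(seed=11)   # 516 specimens, defaults
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    grid, specimens, info = sd.simulate_dataset(params)
    fit = gamm.fit_model(info["covariates"], specimens)

print(gamm.wald_tests(fit).round(3).to_string(index=False))
r2m, r2c = gamm.r2_nakagawa(fit)
print(f"year variance ± sd: {fit.sigma2_year:.3f} ± {fit.sd_year:.3f}")
print(f"residual variance ± sd: {fit.sigma2_resid:.3f} ± {fit.sd_resid:.3f}")
```

prints (abbreviated):

```
                      term  estimate     se  statistic stat_type     p
              rel_min_temp    -5.452  2.358     -2.313         t 0.021
    rel_min_temp:mean_temp     1.634  0.158     10.376         t 0.000
    rel_max_temp:mean_temp    -1.328  0.153     -8.703         t 0.000
rel_min_temp:recent_precip     0.190  0.017     11.390         t 0.000
rel_max_temp:recent_precip    -0.191  0.015    -12.590         t 0.000
                 tarsus_mm     0.965  0.290      3.322         t 0.001
     s(latitude,longitude)       NaN    NaN      2.432         F 0.002

year variance ± sd: 1.126 ± 1.061
residual variance ± sd: 27.905 ± 5.283
```

The single-replicate estimates scatter around the generative truths
(interactions 1.57, −1.25, 0.20, −0.17; variances 0.713 and 28.972);
averaging over replicates recovers them — that recovery is what the
acceptance suite quantifies. The positive `rel_min_temp:mean_temp`
estimate reproduces the qualitative finding that the RTE–SA association
reverses sign across the mean-temperature range.

A command-line pipeline wraps the same stages:

```bash
billclim all --seed 3 --out runs/demo         # simulate → covariates → fit → report
billclim fit --config config.yaml --bodysize wing
```

`billclim all` writes the fixture bundle (NetCDF climate + specimen
CSV + ground-truth JSON), the covariate table, a coefficient table,
figures (interaction surfaces with a 99.9% kernel-density support mask;
conditional-effect lines at the 10th/90th moderator percentiles), model
and diagnostics JSON, and a recovery summary against the simulation
truth.

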