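# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator and its limits, and the design decisions made
where the problem was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Covariate construction

**Buffer means.** A monthly value at a locality is the equal-weight
mean over grid cells whose *centers* fall within a great-circle radius
(default 15 km; haversine on a sphere of radius 6371.0088 km) of the
point. Area-exact partial-cell clipping is deliberately out of scope:
at ~4 km cells and a 15 km radius the buffer holds ~37 cells and the
center-in/center-out difference is far below the climate noise, and the
equal-weight rule is exactly checkable against a brute-force
enumeration (which the tests do). Missing (NaN) cells are excluded; an
error is raised only when every cell in the buffer is missing. A radius
of 0 returns the containing cell.

**Windows.** All covariates use the summer months April–August of the
five *calendar* years before the collection year, regardless of the
collection month — a specimen taken in September 1930 and one taken in
April 1930 see the same 1925–1929 window. The alternative (treating an
in-progress summer as "year 0") is excluded by this calendar-year
convention; it is a documented reading, not a fact about the original
procedure.

**RTE.** Relative temperature extremity is
(prior-year summer mean − mean of the five yearly summer means) / SD.
The defining sum runs over yearly terms, so the default denominator is
the sample SD (n−1) of the **five yearly summer means**
(`sd_mode="yearly"`); the SD of all 25 monthly values is available as
`sd_mode="monthly"` because the source prose supports both readings.
Sample (n−1) SDs are used throughout — n is 5 or 25, so the estimator
choice is material. A zero denominator (constant climate) raises a
degenerate-locality error rather than returning ±inf.

## Bill surface area

SA = π·r·s with r = (w+d)/4 and s = √(r²+l²): the lateral surface of a
right circular cone whose radius averages the semi-width and
semi-depth. The bill-morphology literature contains several cone-type
variants; the formula is therefore a single pluggable function
(`bill_surface_area(..., formula=)`), and everything downstream relies
only on SA being a smooth, monotone, degree-2 homogeneous composite of
(l, w, d). For l=8, w=d=4 the formula gives 2π√68 = 51.8125 mm².

Specimen filters: seasonal window 15 March–30 September and year range
1900–1950, both read inclusively; subspecies restricted to the two
study forms; records with missing sex, coordinates or any of the four
linear measurements are dropped with a one-line reason code. Filtering
is idempotent.

## The GAMM

The model is Gaussian with identity link:

SA_i = x_i'β + f(lat_i, lon_i) + u_{year(i)} + ε_i,
u ~ N(0, σ²_year), ε ~ N(0, σ²).

**Fixed design** (14 columns): intercept; RTE_min; RTE_max; mean
temperature; RTE_min×mean temp; RTE_max×mean temp; temperature SD;
recent precipitation; RTE_min×precip; RTE_max×precip; collection month
(numeric — it carries a single degree of freedom); subspecies
(treatment-coded, reference *pinosus*); body size (tarsus by default,
wing chord as the alternative proxy); sex (reference female).
Covariates enter in raw units so coefficients are per-unit
interpretable; an optional standardization flag exists for
conditioning. Rank deficiency is detected by pivoted QR and reported
with the aliased column names.

**Smooth.** Low-rank thin-plate regression spline on raw (lat, lon)
degrees with the radial kernel r²·log r: the kernel matrix over all
data points is eigen-decomposed, the k leading eigenvectors (by
magnitude) retained, and the 3 polynomial-orthogonality constraints
absorbed, leaving k−3 penalized columns plus the null space {1, lat,
lon}. Default k = 30 — well above the effective dimension the data
select, so the truncation is not binding. The basis is isotropic in
degrees; at this (~5°) extent a degree of longitude is ~0.8× a degree
of latitude, a mild anisotropy accepted and documented rather than
corrected.

**Mixed-model form and REML.** The penalized block is reparametrized so
its penalty is the identity and treated as a random-effect block; REML
then estimates two variance ratios γ = (σ²_smooth, σ²_year)/σ², with σ²
profiled out analytically. Each criterion evaluation uses Woodbury
identities (cost O(n·q²), q = number of random columns), so a full fit
at n = 516 takes a fraction of a second. The profiled criterion can be
extremely flat in log-γ with shallow interior minima, so the simplex
search is seeded from the best points of a coarse 8×8 grid over log-γ;
variance ratios pinned at the box boundary (1e±8) are flagged in the
fit metadata, and a ratio of exactly 0 can be imposed to obtain the
OLS/no-component limits used by the tests. On a shared fixture the fit
agrees with R's `mgcv::gam` (tp smooth + random-effect smooth, REML) to
~4 decimals on every non-intercept coefficient and to ~6 significant
figures on the variance components.

**edf convention.** The smooth's null space is {1, lat, lon} (dim 3),
but the constant is shared with the model intercept, so the design
carries centered lat/lon as unpenalized columns and the *reported*
smooth edf is 3 + trace of the hat over the penalized block: it tends
to 3 as the penalty → ∞ and to k as the penalty → 0. `mgcv` absorbs
the constant via its sum-to-zero constraint, so its smooth edf equals
ours minus exactly 1. Residual df for Wald tests is n minus the total
trace (no double counting of the intercept).

**Inference.** Coefficient covariance is σ²·(C'C + D)⁻¹ — the standard
posterior covariance of the penalized fit, whose fixed-effect block
equals the GLS covariance. Fixed terms get t = β̂/SE with the residual
df above; the smooth gets an approximate F: the quadratic form of all
smooth coefficients against the pseudo-inverse of their covariance,
divided by the smooth edf, referred to F(edf, df_resid). Marginal and
conditional R² are the mixed-model variance partitions
var(η_fixed)/(var(η_fixed)+σ²_year+σ²) and its conditional analogue;
the smooth contribution is counted in the "fixed" predictor because a
single marginal R² is reported with no separate smooth partition.

**Moran's I** uses inverse great-circle-distance weights, zero
diagonal, no row standardization — the most common convention for this
diagnostic; weights are configurable and a hand-built matrix can be
passed directly. The analytic p is the two-sided normal approximation
with E[I] = −1/(n−1) and the randomization-assumption variance
(normality variance available); a permutation p is optional. Coincident
points would produce infinite weights; they are capped at the largest
finite weight with a warning. The analytic test calibrates to a ~5%
null rejection rate at α = 0.05 on n = 100 fixtures (checked over 1000
replicates).

**GVIF** uses the determinant-ratio form on the correlation matrix of
the non-intercept columns; one-column terms reduce to the classical
VIF, and GVIF^(1/2df) is reported alongside.

**Concurvity caveat.** When a covariate is (nearly) a deterministic
function of space — under the default synthetic climate, mean
temperature is driven by latitude alone — the spatial smooth absorbs
part of its effect and the penalized estimate is attenuated. This is a
property of penalized spatial regression (mgcv behaves identically),
not an implementation artifact; the interaction terms, which carry
year-level variation, remain well identified. The Bergmann's-rule
helper (body size ~ mean temperature with the same smooth + year
structure) recovers a generative slope when the temperature field has
non-spatial variation and is honestly attenuation-prone when it does
not.

## Synthetic data

The generator defines the study conditions; its defaults are fixed
once:

* **Grid**: 0.04° cells over lat 34–40, lon −123 to −118 (a
  California-like extent), complete months, years from six years before
  the first collection year through the last (1894–1950 by default).
* **Temperature**: annual-mean level 14.3 °C at the southern edge,
  −1.6 °C per degree northward (latitude is deliberately the sole
  deterministic spatial driver — enough to induce the spatial
  confounding the smooth must absorb), seasonal cosine of amplitude
  8 °C peaking in July, a year-level anomaly (SD 0.75 °C) shared by all
  months of a year, and cell-month noise (SD 0.5 °C). tmin/tmax are
  tmean ∓ a positive half-range (6 °C) with independent year-level
  anomalies (SD 0.4 °C) — this guarantees tmin ≤ tmean ≤ tmax
  everywhere *by construction* and keeps the two RTE measures from
  being perfectly collinear. Resulting 5-year summer means span roughly
  10–19 °C across specimens.
* **Precipitation**: log-normal around 18 mm/month with a year-level
  log-SD of 1.0 (anomalies truncated at 2.5σ to avoid implausible
  >200 mm summer tails) plus month- and cell-level log-noise; the
  prior-summer precipitation covariate lands near 4 and 61 mm at its
  10th/90th percentiles.
* **Response**: SA = full fixed design × the published coefficient
  estimates (generative intercept 90 mm², chosen so the linear
  predictor stays positive over the covariate envelope; it implies a
  ~12 mm culmen) + a full-period sin×cos spatial surface (amplitude
  3 mm²; genuinely nonlinear, so the smooth — not its null space —
  must capture it) + year intercepts with variance 0.713 + residual
  noise with variance 28.972. Responses are conditioned on SA > 0:
  residual redraws first, full specimen redraws if the linear predictor
  leaves no room (~10⁻⁵ of specimens at defaults, so recovery is
  unaffected).
* **Specimens**: localities uniform over the extent (an optional
  clustered mode exists; no attempt is made to match the original
  sampling map), dates uniform over 15 March–30 September, sexes 50/50,
  subspecies 60/40, tarsus ~ N(20.5, 0.8²) mm, wing ~ N(76, 3²) mm.
  Bill dimensions are back-solved from SA with fixed aspect ratios
  w/l = 0.5 and d/l = 0.55 (per-subspecies configurable): with
  c = (w/l + d/l)/4, SA = π·c·√(c²+1)·l², so the scale l is closed-form
  and `bill_surface_area(l, w, d)` returns the generated SA to
  round-off.

**What the generator does not emulate** — topography and coastal
effects, PRISM's interpolation physics, realistic spatial clustering of
collectors, measurement error in the calipers, and any real covariate
correlation structure beyond what the shared climate anomalies induce.
Consequently the synthetic marginal R² (~0.9) is much higher than in
real data of this kind, where the RTE measures are more strongly
mutually correlated and effects partially cancel; passing recovery
tests demonstrates the estimator is correct under the model's
assumptions, not that real data meet them.

## Problem sizes

Chosen as the package's standard verification workloads:
the recovery suite fits 90 replicate studies of 516 specimens on a
3°×3° extent (variance-component recovery is extent-independent; the
reduced extent keeps each replicate under a second); CI coverage uses
200 replicates of 200 specimens; Moran calibration uses 1000 permuted
fixtures at n = 100; the acceptance script uses 100 full-extent
replicates for coefficients plus 200 reduced-extent replicates pooled
for variances. The mgcv cross-check runs one 200-specimen fixture.

## Known limitations

* Gaussian identity-link only; no temporal smooths or model selection.
* The smooth is isotropic in raw degrees (see above).
* Approximate F for the smooth and the residual-df convention are
  conventional choices; other software makes slightly different ones.
* Conditional-effect and surface predictions evaluate the smooth at the
  data centroid (random effects at zero); averaging over observed
  locations would shift the intercept of those figures but not the
  slopes or interactions.
* Percentiles use linear interpolation between order statistics
  (`np.percentile` default); the 10th percentile of 1..100 is 10.9
  under this convention.
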