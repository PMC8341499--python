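# Methods

## Scope and data model

`windshy` implements a displacement ("meso-avoidance") analysis of GPS
telemetry around wind turbines.  Its in-memory containers are pandas
DataFrames with documented schemas (telemetry fixes, flight segments,
proximity records) plus small frozen dataclasses for turbines, SCADA
status records and fitted-model summaries.  All planar coordinates are
projected metres; altitudes are metres above sea level (asl); times are
UTC.

## Fix-level quality control

Four rules are applied in a fixed order — HDOP, missing altitude,
altitude ceiling, night — so that each excluded record carries exactly
one reason and QC reports reconcile additively.  Defaults: retain fixes
with `hdop < 3.5` (strict), altitude present and `<= 6000` m, and
timestamp within `[sunrise, sunset]` (closed interval) at the fix's own
latitude/longitude/date.  Sunrise and sunset come from the NOAA
low-precision solar equations at the conventional rise/set altitude of
−0.833° (refraction plus solar semi-diameter); polar day retains all
fixes of that date, polar night none.  The solar routine is verified in
the test suite against an independent ecliptic-coordinate solar-position
oracle scanned at 20-s resolution (agreement within 2 min).  VDOP is
read when present but never filtered on.  The choice of geometric
−0.833° rather than civil twilight is configurable; a fix exactly at the
rise/set instant is retained.

## Approach geometry

Distances are *2-D-first*: the closest pass of a flight line to a hub is
located in the horizontal plane (clamped orthogonal projection onto the
segment), altitude is interpolated linearly at the pass fraction, and
the 3-D distance follows from the horizontal separation and the altitude
difference to the hub.  This is deliberately not the true 3-D minimum
over the segment; it is the field convention for this analysis and is,
if anything, conservatively low.  Tag altitudes (asl) and hub heights
(agl) are put on a common asl datum via the tower base elevation before
differencing; the datum handling is a documented switch.  Zero-length
segments are legal and reduce to point distances (robustness to
stationary birds).

## Dataset assembly

*Fix-based before/after table*: each QC-passed fix pairs with its single
nearest turbine by 2-D distance; pairs beyond a 1,000-m buffer are
dropped and counted.  Phase is BEFORE when the fix precedes the
turbine's operation date (construction time folds into BEFORE, which is
conservative for displacement tests) and AFTER from the operation
instant onward.  *Segment-based after-operation table*: consecutive
same-bird GSM fixes ≤ 300 s apart form straight flight segments; each
segment pairs with the turbine of smallest closest-approach distance,
the pass time (`start + fraction × duration`) is rounded to the nearest
3 h (90-min ties round up) and joined to SCADA by exact key.  Records
with missing SCADA, nodata habitat pixels, or pre-operational pass times
are dropped and counted; every drop counter is additive so the input
reconciles exactly.

Descriptive summaries report mean, sample sd, the empirical 2.5–97.5%
data range (labelled `range95` — it is a data spread, not a standard
error band), counts of records within k rotor diameters (strict `<`),
and low quantiles by farm × blade state using linear interpolation
between order statistics.

## Mixed models

All candidate models are Gaussian linear mixed models of the 3-D
distance with independent crossed random intercepts for wind-farm,
turbine and bird identity, fitted by maximum likelihood (not REML) so
information criteria are comparable across fixed-effect structures.
Estimation delegates to `statsmodels` `MixedLM` (variance components
with a single all-encompassing group); the package recomputes
`AIC = −2ℓ + 2·df` and `BIC = −2ℓ + df·ln n` with
`df = n_fixed + n_variance_components + 1`, matching the convention of
the R `lme4`/`lmer` ML fits this layer mirrors (the test suite verifies
log-likelihood agreement with an independent numerically-maximised
balanced one-way likelihood, and the fitted criteria against the
identities on every fit).

GET scores enter as numeric covariates (single slopes), operational
phase and blade motion as 0/1 indicators.  The before/after candidate
set enumerates 12 models (null; three singles; three pairs without and
with their two-way interaction; the additive triple; the saturated
triple), the after-operation set 27 models over four main effects with
the listed interaction structures; interactions are only ever included
alongside all their constituent main effects.

Selection: the model minimising both AIC and BIC wins outright; on
discord the BIC winner is chosen (parsimony; an `aic` rule is available
behind a flag); residual ties break toward fewer parameters.

p-values are Wald normal approximations and are flagged as such in every
output (`p_value_method`); with thousands of observations and modest
random-effect counts the difference from Satterthwaite-style df is
negligible, and no dedicated implementation is shipped.  Random factors
with fewer than two levels in the complete-case data (e.g. a single farm
in a small fixture) are dropped with a warning rather than fitted at the
boundary; variance components estimated at the boundary are reported as
0 with a flag, and non-positive-definite Hessians yield NaN standard
errors rather than silent nonsense.  Optimisation is deterministic:
L-BFGS with fixed tolerances and a Powell fallback only on
non-convergence.

Variance decomposition follows Nakagawa & Schielzeth: σ_f² is the
variance (ddof = 1, matching R's `var`) of the fixed-effects linear
predictor over the modelled rows; marginal and conditional R² and the
per-factor shares of explained variance
(`τ_g / (σ_f² + Σ τ)`) follow.  The algebraic inverse
`σ_f² = marginal · Σ τ / (conditional − marginal)` is provided to
reconstruct σ_f² from published tables that print both R² values and the
τ's.  Partial-effect grids evaluate the fixed linear predictor over a
focal grid with other predictors at observed means (or pinned), random
effects at zero, and delta-method 95% bands from the fixed-effect
covariance.

## Synthetic study systems

The generator emulates the four input streams with the statistical
structure the analysis assumes.  Defaults mirror the study system:

* **Landscape** — 12 × 8 km of 50-m pixels; a Gaussian random field
  smoothed to a 400-m autocorrelation length, rank-quantised to GET
  scores 1–10 with a mildly right-skewed frequency profile (mass peaking
  at scores 3–5, ~14% at 6+ by design choice; the real surface is not
  uniform and preferred habitat is the minority).
* **Farms** — presets of 33 turbines (80-m hubs, 40-m blades, operational
  2016-11-07) and 66 turbines (73-m hubs, 57.5-m blades, operational
  2018-06-01, the midpoint of the real farm's commissioning window),
  laid out as jittered grids at 350-m spacing with base elevations in
  650–750 m asl; `scaled_farms()` provides reduced layouts for fast runs.
* **Weather/SCADA** — per-farm AR(1) Gaussian series (3-h step,
  persistence 0.7) mapped through a Weibull(scale 8 m s⁻¹, shape 2)
  marginal, small per-turbine jitter; rotors stop below the 3.5 m s⁻¹
  cut-in or during maintenance records sampled at 2%; rotor speed is
  classified against the wind value as stored (2 dp) so wind/rotor pairs
  are always internally consistent.
* **Movement** — a biased correlated random walk in independent "bouts"
  (visits): 60 fixes at the GSM 1-min cadence (Argos 1-h), started at
  random daytimes through a 3-year period at random locations near a
  farm.  Step lengths are Gamma(2) with 500-m mean; candidate headings
  are weighted by heading persistence (κ = 0.5), habitat attraction
  (α·GET, α = 0.25), a centre pull, and — only after the nearest
  turbine's operation date — an exponential repulsion
  β·exp(−d/ρ)·(1 − w·wind/12) with β = 4, ρ = 300 m, w = 0.5.  The
  repulsion is the simplest mechanism producing the analysis's
  qualitative structure (displacement post-operation, weakened in
  preferred habitat and at high wind); it is a modelling convenience,
  not a claim about eagle cognition.
* **Observation** — HDOP from a lognormal with an 8% heavy component
  ≥ 3.5 (so the QC filter is exercised), GPS noise 6 m per HDOP unit,
  altitude noise 15 m with 2% missing, latitude/longitude from a fixed
  documented affine anchoring (not a real projection) so the daylight
  filter operates.  True positions are retained beside the observed
  columns for truth-based validation.

The bout design is deliberate.  The analysis model treats records as
exchangeable given farm/turbine/bird intercepts, which presumes data
accrue over many quasi-independent visits, as they do over a multi-year
field study.  Long continuous tracks at 1-min cadence violate that
structure and produce a cluster design effect: in piloting, slow
within-visit mixing inflated the true sampling sd of the displacement
coefficient to ~2× the model SE (≈65–75% CI coverage).  Short visits do
not help (fewer records per visit raises the within-visit intraclass
correlation toward 1); fast mixing within longer visits does, because a
visit's mean distance then averages over the stationary distribution.
The shipped defaults give measured null coverage of ~88–90% at 20–40
replicates, within the binomial tolerance the acceptance checks allow.
Passing tests on these data therefore demonstrate correctness of the
pipeline and approximate calibration under the model's own assumptions;
they do not show that real 1-min telemetry satisfies those assumptions —
with strongly autocorrelated field data the model's CIs should be
expected to be anti-conservative, exactly as for the original analysis
design.

What the generator does **not** emulate: terrain (base elevations are
random, flight altitude is not terrain-following), orographic/thermal
uplift physics, seasonal or diurnal wind cycles, behavioural states
(perching vs flight), collision events, and tag duty-cycle gaps.

## Problem sizes

The test suite and the acceptance script run the replicate experiments
at ~10,000 fixes per world on reduced 10+16-turbine layouts (the full
33+66 presets remain available and tested for layout properties); the
replicate counts are 20 per condition in the tests and 12 in the
acceptance script.  These sizes were chosen so a complete run stays in
the minutes range on a single CPU while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* Wald (normal) p-values only; no Satterthwaite/Kenward–Roger df.
* The farm random factor has two levels in the emulated system; its
  variance is weakly identified, and fits frequently pin it at the
  boundary (reported as 0 with a flag) — also true of the original
  two-farm design.
* Exact-key SCADA joins: a record whose rounded time has no SCADA row is
  dropped, not interpolated.
* The 2-D-first distance convention understates true 3-D clearance for
  steeply climbing or descending passes.
* Deposited field telemetry is not bundled; analyses of the real system
  require the user to supply those files, and the descriptive
  reproduction checks then compare against the published values.
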