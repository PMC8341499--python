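# windshy

Do large soaring raptors keep their distance from wind turbines once the
blades start turning?  `windshy` is a Python pipeline for answering that
question from GPS telemetry: it turns raw tag fixes, per-turbine metadata,
3-hourly SCADA records and a habitat-preference raster into 3-D
turbine-approach distances, before/after-operation displacement models,
and blade-motion/wind-speed models — the analysis design used to study
dispersing golden eagles *Aquila chrysaetos* at two Scottish wind farms.

It is aimed at movement ecologists and wind-farm impact assessors who
want the full chain — quality control, approach geometry, dataset
assembly, mixed-model selection, variance decomposition — as tested,
reusable library code, plus a synthetic-data generator that emulates the
whole study system so every stage can be validated without field data.

## The analysis in brief

**Response.**  For each retained GPS fix (or flight line between
consecutive fixes ≤ 5 min apart), the closest pass to the nearest turbine
hub is found in the horizontal plane; flight altitude is interpolated at
that pass, and the 3-D distance follows by trigonometry,

    d3d = sqrt( d2d² + (alt − hub_alt)² ),   hub_alt = base elevation + hub height.

**Quality control.**  Fixes with HDOP ≥ 3.5, missing or implausible
(> 6 km) altitude, or timestamps between local sunset and sunrise are
removed (each exclusion attributed to exactly one rule, in that order);
only fixes within 1 km of a turbine enter the models.

**Models.**  Gaussian linear mixed models of `d3d` with crossed random
intercepts for wind-farm, turbine and bird identity, fitted by maximum
likelihood.  Two fixed-effect candidate sets are enumerated: 12 models
over {turbine GET score, operational phase, location GET score} for the
before/after analysis, and 27 models over {GET scores, blade-motion
status, hub wind speed} for the after-operation analysis.  Selection is
by AIC and BIC (BIC wins on discord).  Explained variance is decomposed
with Nakagawa marginal/conditional R²:

    R²_marginal    = σ_f² / (σ_f² + Σ τ + σ²)
    R²_conditional = (σ_f² + Σ τ) / (σ_f² + Σ τ + σ²)

where σ_f² is the variance of the fixed-effects linear predictor, τ the
random-intercept variances and σ² the residual variance.

**GET scores.**  Habitat preference enters through the Golden Eagle
Topography model surface: integer scores 1–10 on 50-m pixels (6+ is
increasingly preferred).  The surface is consumed, never derived: a
turbine's score is the mode of its pixel and the four edge-adjacent
neighbours (ties to the highest score), a record's score is the single
pixel under it.

## Worked example

```sh
python examples/02_qc_and_distances.py
```

prints, for a seeded synthetic study system (two farms, seven tagged
birds, default avoidance strength):

```
QC report (counts by first failing rule):
{ "input": 2850, "retained": 1604,
  "excluded": { "hdop": 275, "missing_altitude": 47,
                "altitude_gt_max": 0, "night": 924, "other": 0 } }

460 fixes within 1 km of their nearest turbine

3-D distance to the nearest hub by operational phase (m):
         mean     sd  range95_lo  range95_hi    n
after   671.6  248.8       175.8       993.4  226
before  535.6  294.6        80.9       978.9  234
```

The QC report reconciles exactly (1604 + 275 + 47 + 924 = 2850); the
136 m larger post-operation mean is the injected avoidance effect showing
through the full pipeline.  `examples/03_model_selection.py` continues
with the 12-candidate mixed-model table, where the same run selects a
model whose `postop` coefficient is 137.0 m (95% CI 74.1–199.9) — the
displacement estimate with repeated-measures structure accounted for.
The other examples cover bundle generation and variance decomposition.

## Command line

The same chain is scriptable from a shell:

```sh
windshy run --seed 7 --outdir out/           # simulate + full analysis
windshy qc --telemetry fixes.csv --outdir out/
windshy dataset --fixes out/qc_fixes.csv --turbines turbines.csv \
    --raster get.asc --scada scada.csv --outdir out/
windshy fit --records out/before_after_records.csv --family before_after --outdir out/
```

Thresholds (HDOP cut-off, buffer, segment gap, …) live in an optional
YAML config; every stage writes a manifest with the configuration echo
and input checksums, and all record drops are accounted in `drops.json`.

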