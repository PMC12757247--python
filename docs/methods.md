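# Methods

This note documents the model, its assumptions, the synthetic-data design,
and the numerical choices, in the package's own terms.

## Scope and data situation

The package reimplements a greenhouse tomato yield study as a testable
pipeline. The original analysis ran a full APEX build (v.1501) driven by
two years of daily greenhouse records; neither the daily weather nor the
per-harvest yield records are public. What *is* published: monthly means
of external weather, season-level greenhouse temperature/humidity
means ± SD per regime, four cultivar parameter sets, four observed total
dry fruit yields, six microclimate regressions, and scenario-level
monthly greenhouse temperature targets. The package therefore (a)
regenerates daily weather from the published summaries, and (b) replaces
APEX with a from-scratch "EPIC-family lite" daily engine restricted to
the processes the published parameters actually exercise. Components are
what they are: the engine is not a wrapper and does not claim APEX
equivalence.

## Synthetic weather generator

The generator emulates exactly the published summary statistics, nothing
more:

* Each variable, each day, is an independent draw from a normal
  distribution truncated at physical bounds (humidity in [0, 1];
  radiation, precipitation, wind ≥ 0), centred on that month's published
  mean.
* Published SDs exist only for temperatures and humidity (season-level);
  they are applied to every month of the season. Variables without a
  published SD use a day-to-day coefficient of variation of 0.25, a
  typical mid-latitude summer dispersion for daily radiation and wind;
  this choice fixes realistic spread while matching printed means.
* tmax/tmin draws that cross are swapped (then clamped if a scenario
  offset re-crosses them).
* One master seed fans out per variable through a CRC-keyed
  `SeedSequence`, so adding a variable never perturbs another variable's
  stream.

Not emulated: autocorrelation (heat waves arrive as independent hot
days), cross-correlation (rain days are not darker), within-month trends,
and diurnal structure. Tests passing on this generator therefore
demonstrate correctness of the *model pipeline* under the published
marginal statistics, not skill against real correlated weather.

The external table prints its radiation column as kWh/m²; the values
(14–24) are implausible for daily kWh and exactly right for MJ m⁻²
day⁻¹, so the package treats them as MJ-scale (`SR_TO_MJ = 1.0`,
configurable to 3.6 if a source truly reports kWh). The two mid-season
rows of the external monthly table are labelled "April" between June and
August; they are stored as July.

## Microclimate model

The six published regressions are immutable constants; evaluation is the
literal polynomial, with humidity clamped to [0, 1] and predicted tmin
clamped down to predicted tmax (logged) since the two are independent
regressions. Refitting follows the published selection procedure:
two-sided Pearson-significance screening at α = 0.05, then greedy
collinearity exclusion at |r| ≥ 0.5 keeping the member more correlated
with the response (0.5, "strong", matches the published exclusion of
precipitation at |r| = 0.54 with radiation), then OLS on powers 1..L of
each survivor. The published models keep some variables only at a single
power (e.g. tmin enters the tmax models only squared); no pruning rule
was published, so per-term choices are an explicit `term_spec` override
rather than an automated search. Cross-validation folds are
contiguous-in-time blocks by default (the data are a time series), with a
seeded random option. The published R² values were computed on the
unpublished 175-day dataset and are carried as metadata only.

In-greenhouse radiation is not predicted by the regressions, but the crop
engine needs it, so greenhouse days carry `sr` = envelope transmission ×
outside radiation. The transmission factor (`SR_TRANSMISSION = 0.65`) is
the one global scale constant of the engine. 0.65 is a textbook effective
shortwave transmission for plastic multi-span houses with structural
shading; it was fixed during model construction by checking that the
engine's uncalibrated yields land on the observed single-digit Mg/ha
scale for all four cases (the same role overall fine-tuning played in the
original parameterization), and it is not revisited per case — per-case
agreement is the job of the WA calibration.

## Crop engine

Daily loop, in order: heat units, canopy, stresses, water balance,
growth. Functional forms are the standard EPIC family choices:

* **Phenology**: ΔHUI = max(0, (tmax+tmin)/2 − TG)/PHU. The engine uses
  tavg = (tmax+tmin)/2 throughout, the only temperature statistic the
  records support. HUI may exceed 1 in hot seasons; LAI and
  radiation-use efficiency are zero past HUI = 1 (growth stops), while
  the run continues to the configured harvest date.
* **Canopy**: LAI = DMLA · f(HUI) with the sigmoid
  f(x) = x/(x + exp(l1 − l2·x)); (l1, l2) solved in closed form from the
  two decoded DLAP points (each point gives a linear equation in
  (l1, l2); residual checked < 1e−9). Past HUI = 0.9 the LAI declines as
  ((1−HUI)/0.1)^RLAD; with RLAD = RBMD = 0.1 the decline is mild,
  consistent with plants remaining green at harvest.
* **Temperature stress**: TS = sin(π/2 · x), x = (tavg−TG)/(TB−TG),
  clamped to [0,1] and zero outside x ∈ (0, 2) — 1 at the optimum, 0 at
  the base, symmetric decline beyond the optimum.
* **Light and growth**: PARi = 0.5 · SR · (1 − exp(−0.65·LAI));
  ΔB = 0.001 · WA_eff · PARi · min(TS, WS) Mg/ha (most-limiting stress,
  the EPIC convention), WA_eff declining past HUI = 0.9 like the LAI.
* **Water**: Hargreaves-type PET = 0.0135·(tavg+17.8)·SR/2.45; demand =
  PET × cover with cover = 1 − exp(−0.65·LAI); AET = min(demand,
  available water) from a single-layer 150 mm bucket starting full
  (round-number loam-scale defaults; only the soil series name was
  published); automatic irrigation refills the bucket daily, limited by
  the seasonal cap when one is set; WS = AET/demand. Greenhouse
  precipitation is 0 and wind 1 m/s by construction. There is no bare-
  soil evaporation term, so simulated seasonal irrigation (~100–130 mm)
  is below the ~400 mm the published water-use-efficiency values imply;
  WUE magnitudes are therefore engine-specific and only their scenario
  *changes* are meaningful here.
* **Yield**: dry fruit yield = HI × final biomass, exactly.

The simulated window is the treatment period of the trials: seasons are
generated 1 May–31 August, the crop runs from 18 May for 77 days (the
final harvest of the trials was on the 77th treatment day). With PHU =
2000 the 77-day window reaches HUI ≈ 0.75–0.83, i.e. harvest-by-date
before maturity, as in the trials.

A consequence of the fixed forms worth stating: over the 77-day window at
*fixed* parameters, hotter weather can slightly raise yield (faster
heat-unit accumulation builds canopy earlier and outweighs the shallow
sine stress near the optimum). Over the full season the effect reverses —
the hot house exhausts its heat units early and loses canopy — so the
directional heat-effect property is stated and tested on full-season
runs. The observed heat-stress yield losses enter the four-case
comparison chiefly through the heat-regime parameter sets (lower WA, HI,
DMLA), as they did in the original parameterization.

## Calibration

Per case (accession × regime), WA is bisected within ±30% of its
published value against the observed total dry fruit yield until
|percent bias| ≤ 1% (strictly inside the published sub-3% envelope),
relying on the engine's strict monotonicity of yield in WA (checked; a
detected decrease raises). The simulated yield inside the bisection is
the mean over 8 seeded weather realizations of the treatment window, so
the calibrated WA targets the expected yield rather than one weather
draw. Unreachable observations return the nearer bound with a flag
rather than an error.

Metric definitions follow the published usage: R² is the coefficient of
determination 1 − SSres/SStot (on the four published yield pairs this
gives 0.990 ≈ the printed 0.99, whereas squared Pearson correlation gives
0.9995 — the printed value selects the definition). Two published
evaluation numbers are not reproducible from the printed table and are
documented rather than asserted: the table's RMSE of 0.03 Mg/ha (the four
printed pairs give 0.163; plausibly computed per harvest event or in
other units) and the second decimals of two percent-bias rows (−2.34 /
−2.93 printed vs −2.31 / −2.91 recomputed from the rounded yields). The
harvest-index column has one analogous cell: 1.5/3.16 rounds to 0.47,
not the printed 0.48 (evidently computed from unrounded weights); the
acceptance test states the printed value and is expected to fail on that
cell.

## Scenarios

Warming is emulated, not ingested: for each month a 2×2 root solve finds
the additive external tmax/tmin offsets that put the regression-predicted
greenhouse means onto the published scenario targets; scenario offsets
are the difference between the solved target state and the solved
historical state, so the emulation is anchored to the same pipeline it
perturbs. Mean-day evaluation ignores a small Jensen term from the
squared-tmin regression term (≈0.005·Var(tmin) ≈ 0.08 °C, far below
sampling noise). Scenario runs use heat-regime parameter sets (the
published scenario baseline yields match the heat-regime evaluation
rows), PHU overrides of 2600/2800, per-accession annual irrigation caps
of 4000/6000 mm (which never bind at greenhouse scale — they matter only
as contracts), inert CO₂ at 360 ppm, and ten years by default with
per-year seeds derived from the master seed.

The published scenario *magnitudes* (HR17 ≈ −1.2 Mg/ha, HR24 ≈ +1.3
Mg/ha) depend on APEX internals and GCM daily weather not reproducible
here; the package treats the comparison directionally. In this engine
both accessions lose yield under warming, HR17 roughly −1.0 Mg/ha and
HR24 substantially less in relative terms, preserving the published
ordering (HR24 more heat-resilient) though not HR24's absolute gain —
that gain requires the longer, hotter season to *benefit* a cultivar via
mechanisms (e.g. extended fruiting with PHU extension under APEX's
phenology) that the 77-day fixed-window engine does not represent. This
is a known limitation, stated rather than tuned away.

## Problem sizes

All computations are desk-scale by design: seasons are ≤ 123 days,
calibration uses 8 weather replicates per case, scenario analyses use
10-year runs, and the statistical direction checks use 10 seeded
replicates of 3-year runs. The full test suite runs in a few seconds.
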