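# Methods

## Model structure and assumptions

The simulator is a deterministic compartmental (stock-and-flow) model of the
adult (20+) population, stratified by sex. Three mutually exclusive glycemic
stocks — normoglycemia, prediabetes, diabetes — cover the whole adult
population. Structural flows are NG→preDM, preDM→NG (remission), preDM→DM,
per-stock all-cause mortality, and a demographic inflow that enters NG only.
Diabetes has no remission flow: prevalence can fall only through mortality
outpacing onset, which is why mortality-reducing interventions (diabetes
self-management education, DSME) *raise* diabetes prevalence while lowering
diabetes deaths — the model reproduces this prevalence/incidence distinction
by construction.

Integration is explicit forward Euler at `dt = 1` year (configurable; any
divisor of one year). The reference scheme is fixed rather than adaptive so
that runs are bit-reproducible; a step-refinement test verifies that halving
or quartering the step moves no 2050 prevalence by more than a few tenths of
a percentage point. Within a step the order is: drivers and demography at
the current year → energy balance (weight, BMI, obesity) → glycemic hazards
using the just-updated obesity prevalence → stock update. Obesity is
current-year because it drives onset within the year.

Conservation (change in total population = inflow − deaths) holds to
floating-point rounding at every step and is asserted in the test suite at
1e−9 relative. Stocks that a pathological parameter corner would overdraw
are clipped at zero with a warning rather than an error, so scenario and
sensitivity sweeps do not abort; none of the packaged runs triggers the
clip.

## Energy-balance sub-model

Per sex the model tracks one mean body weight. Resting metabolic rate uses
the classical Harris–Benedict equations (male
66.5 + 13.75·W + 5.003·H − 6.755·A; female
655.1 + 9.563·W + 1.850·H − 4.676·A, kcal/day), multiplied by a sedentary
physical-activity factor `paf = 1.2` to represent non-MVPA expenditure.
MVPA converts to kcal/day with the net-of-rest MET formula
`min/day · (MET − 1) · 3.5 · W / 200`. The annual caloric gap divided by an
energy-density constant (`forbes_k`, default 7700 kcal per kg) gives the
annual weight change; re-evaluating RMR at the current weight each step makes
weight gain self-limiting with a time constant of roughly 1.3 years.

Mean BMI maps to obesity prevalence assuming a normal BMI distribution per
sex with constant, calibrated standard deviation (6.0 women, 5.0 men,
kg/m²). A normal rather than lognormal form keeps the inverse mapping
closed-form, and the mean stays far from the support boundary throughout.
Fruit/vegetable servings carry zero net calories by default (their modelled
effect is on diabetes incidence); a kcal-per-serving override exists.

## Flow modifiers

Obesity and population ageing enter both onset hazards as reference-
normalised power laws, `(ob/ob_ref)^β_ob · (age/age_ref)^β_age`, equal to
one at the 2010 reference conditions. Dietary and physical-activity relative
risks apply to the preDM→DM hazard only, multiplicatively on the hazard
scale with exponents linear in the exposure delta from the 2010 reference:
RR 1.26 per SSB serving/day, RR 0.96 per fruit/vegetable serving/day, and a
calibrated RR per +30 min/day MVPA (fixture value 0.885). Whether obesity
should modify diabetes onset directly or only prediabetes incidence is
genuinely open; we apply it to both stages, which makes the obesity channel
somewhat stronger than a one-stage alternative and is absorbed by the
calibrated exponent. The preDM remission hazard is an unmodified calibrated
constant; the fit drives it near zero (0.002/yr), i.e. essentially all exits
from prediabetes are progressions or deaths under the packaged conditions.

Coverage interventions scale hazards: lifestyle modification multiplies the
onset hazard of the covered preDM fraction by 0.81 (pooled 19% incidence
reduction), DSME multiplies DM mortality of the covered DM fraction by 0.75
(pooled 25% mortality reduction). Scenario coverage switches on at the
scenario start year.

## The packaged Jamaica fixture

No supplementary input time-series are public at usable granularity, so the
fixture's driver series are constructed, not transcribed. Their *shapes*
follow the documented directions of change — MVPA strictly declining
(74 → 35 min/day across 1990–2050), SSB and ultra-processed calories rising,
fruit/vegetable intake slowly declining, mean adult age rising with the rise
concentrated in 2012–2032, background mortality declining, demographic
inflow slowly declining. Their *levels*, together with the free model
parameters, are calibrated so that the baseline run reproduces the published
prevalence trajectory (diabetes 12% in 2018 rising to 15.4% in 2030 and
20.9% in 2050; obesity 28.6% in 2018 rising to 32.1% and 39.2%; women's
obesity 38.4% in 2020 and 48.8% in 2050) and the published scenario response
magnitudes.

Two deliberate consequences of that calibration:

* **Effective, compensation-adjusted exposure units.** Literal calorie
  accounting through the Harris–Benedict/Forbes feedback yields equilibrium
  weight responses of roughly 1 kg per 17 kcal/day of sustained change, an
  order of magnitude stronger than the population responses the published
  scenario tables imply (behavioural compensation, substitution and
  adherence sit between a policy's nominal calories and the population
  steady state). The fixture therefore carries the SSB and UPF series in
  *effective discretionary-calorie* units (tens of kcal/day) and uses an
  effective MVPA MET excess of 0.13 (`mvpa_met = 1.13` in the fixture
  params) rather than a physiological MET of 4, so that simulated responses
  match the published response magnitudes. The library defaults
  (`mvpa_met = 4.0`, 150 kcal/serving) remain physiological; only the
  fixture's calibrated parameter set deviates, and states so.
* **Per-sex obesity levels.** The published per-sex obesity figures (women
  38.4%, men 12.5% in 2020) are inconsistent with the published overall
  obesity (29.2% in 2020) under any plausible population weighting. The
  fixture resolves the conflict in favour of the overall and women's
  trajectories; its male obesity path (≈20% in 2020 → ≈29.6% in 2050) is
  therefore higher than the printed male values.

The residual caloric driver (`other_kcal`) is obtained by exact inversion of
the Euler energy update along the designed BMI paths, so the baseline
obesity trajectory equals its design and scenarios still perturb weight
through the full dynamics. Calibrated glycemic parameters (bounded
multi-start least squares against the anchors; objective tolerance 1e−8):
`h_ng_pre = 0.00638`, `h_pre_ng = 0.002`, `h_pre_dm = 0.0308` (all 1/yr),
`β_ob = 1.7`, `β_age = 0.3`, `hr_pre = 1.1`, `hr_dm = 2.2`,
initial (1990) diabetes share 3.6% and prediabetes share 33% per sex. All
baseline anchors are reproduced within 0.45 percentage points.

## Scenarios

"Magnitude change maintaining the relative trend" is implemented as
multiplicative scaling of the whole post-start trend line; additive
interventions (minutes of MVPA) shift the line by a constant. Composition
order per variable: all scales (multiplicative, order-free), then all adds.
The front-of-package-labelling block scales SSB by 0.934 (its mean caloric
reduction, applied to the discretionary component), UPF by 0.87 and
fruit/vegetables by 1.13, plus a campaign addition of 4 g/day of
fruit/vegetables converted at 80 g/serving; the campaign's MVPA effect is
configurable and off in the built-in bundles (their MVPA effect is the
explicit +15/+30 min). Caribbean scenario bundles start in 2020; the GAP
magnitude search starts in 2010 and scales MVPA and the modifiable caloric
components (SSB, UPF) — scaling the residual intake term as well would be a
~600 kcal/day lever that no population intervention resembles and would
make every grid cell trivially feasible. Prevented DM deaths are reported as
the relative reduction in annual deaths among the DM stock in 2050 versus
baseline.

## Calibration

Weighted least squares (weights 1 or 1/se² when a standard error is given)
rather than a formal likelihood, minimised with scipy's bounded
trust-region-reflective least squares and multi-start (default 5 starts:
the supplied start plus seeded uniform draws within bounds). Effect sizes
with published values (RR 1.26, RR 0.96, lifestyle 0.81, DSME 0.75) are
fixed, not fitted. Parameter-recovery experiments on synthetic bundles
(three survey metrics at four survey years, 1999–2017) recover
`h_ng_pre`, `h_pre_dm` and `β_ob` exactly at zero noise and recover
`h_pre_dm` and `β_ob` within 25% relative error under binomial survey noise
(n = 2500) in the fixed replicate seeds 1–5.

## Synthetic data

Linear annual trends with the study's directions of change; a seeded ±10%
perturbation of each slope makes distinct seeds produce distinct series
without changing any direction. Designed per-sex obesity paths (linear in
prevalence between configurable endpoints) are converted to BMI paths and
closed with the same energy-inversion used by the fixture. Survey
observations are binomial draws at the true simulated prevalence with
`se = sqrt(p̂(1−p̂)/n)`; no design effects or measurement bias, so passing
recovery tests demonstrates identifiability under sampling noise only, not
robustness to survey design effects, self-report bias or model
misspecification.

## Sensitivity analysis

Latin Hypercube sampling via scipy's stratified generator (exactly one draw
per equal-probability stratum per dimension, seeded), linear or
log-uniform per parameter; default ranges ±25% around fixture values with
relative-risk directions preserved. The sensitivity index is the partial
rank correlation coefficient (PRCC: Pearson correlation of rank residuals
after regressing out the other parameters); the univariable mode sweeps one
parameter over 11 grid points. Failed samples (parameter combinations
rejected by validation or producing a simulation error) are recorded and
excluded from summaries with their count reported.

## Numerical choices and limitations

* Euler `dt = 1 yr` reference; quarter-step runs differ by < 0.15 p.p. in
  2050 diabetes prevalence on the fixture.
* Trend queries interpolate linearly between knots; beyond the knot range a
  series either holds its end value or continues its end slope.
* The model carries mean weight per sex, not a weight distribution;
  dispersion exists only in the BMI→obesity mapping. Age enters as one
  aggregate index, not cohorts. Hypertension, tobacco, alcohol and
  macronutrient composition are out of scope.
* Dose–response convexity: every exposure channel composes into the onset
  hazard multiplicatively (`RR^x`, power laws), so the benefit of scaling an
  exposure down by a fraction r is concave in r and the ratio
  delta(50%)/delta(10%) is bounded above by 5, approached in the
  weak-exposure limit (the fixture yields ≈4.9 for SSB). Reproducing a
  ratio strictly above 5 would require a convex (threshold-like) exposure–
  incidence form, e.g. piecewise lookup tables with accelerating slope,
  which this package deliberately replaces by smooth reference-normalised
  power laws. The MVPA→obesity response is linear to within 1% (+30 min
  yields 1.99× the +15 min effect at 2050).
* The GAP feasibility margins on the default grid are a few tenths of a
  percentage point; conclusions from that grid are qualitative
  (infeasibility of the 2025 targets), not precise thresholds.
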