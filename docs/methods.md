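# Methods

## The estimation problem

A mother's fundal height grows roughly linearly through mid-pregnancy
(about 1 cm per gestational week) and then plateaus, but both the level
and the shape of the curve differ markedly between mothers: in serial
antenatal data, women recording the same SFH of 20 cm span roughly ten
weeks of gestational age. A single measurement therefore dates a
pregnancy poorly; a *series* of dated measurements constrains both the
position and the slope of the individual curve, which is the
information the multiple-measures model exploits.

All gestational ages are continuous weeks on a linear clock of exactly
7 days per week, anchored by an early ultrasound (crown-rump length or
biparietal diameter) that is treated as error-free gold standard. The
EDD is the date at which GA reaches `term_weeks` (default 40.0, the
standard obstetric convention; configurable), rounded to the nearest
whole day with half-days rounding forward.

## Cohort rules

A mother enters analysis only with at least 3 serial measurements, all
adjacent pairs at least 14 days apart (exactly 14 is retained). The
rule excludes the *mother*, never individual measurements; whether the
spacing rule should bind any pair or only adjacent pairs is ambiguous
in the clinical convention — adjacent pairs is implemented, since a
sorted series with all adjacent gaps ≥ 14 days has all pairwise gaps
≥ 14 days anyway. Recorded heights are whole centimetres (half-up
rounding at recording time); the CSV reader enforces this.

## Models

**Model 1** `G = a1 + a2·H`, defaults `(4.5, 1.0)`.

**Model 2** is parameterised as the inverse of a logistic height
curve, `G = b3 + ln(H/(b1−H))/b2`: `b1` (cm) is the SFH saturation
asymptote, `b3` (weeks) the GA at the curve's inflection, `b2` (1/cm)
the steepness (midpoint growth velocity `b1·b2/4` ≈ 0.74 cm/week at
the defaults `53.96, 0.055, 24.82`). This is the simplest three-
parameter family that is linear early, plateaus late, and stays
strictly increasing; its valid domain is bounded above by the
asymptote `H < b1` and below by the height at which the inverse GA
becomes non-positive (`b1/(1+e^{b2·b3})` ≈ 11 cm at defaults) —
outside it the predictor raises a domain error rather than
extrapolating.

**Model 3** enumerates the "sets of three" of a series: all index
triples whose first two indices are adjacent, `(i, i+1, j)` with
`j > i+1`, giving `(n−1)(n−2)/2` triples (six for five measures). A
full 3-subset variant is available for sensitivity analysis. Each
triple is predicted two ways:

- eq. 3a, the mean of three single-measure linear estimates
  `cL0 + cL1·H_i` each projected to the triple's last date at one
  GA-week per calendar week;
- eq. 3b, a linear combination of the three heights and the three
  pairwise gradients (cm/week).

The 3b value is used iff it lies in the **closed** interval
`[Gmin, Gmax]`; otherwise the 3a value is used unclamped. Because
different triples end at different dates, each triple's prediction is
projected to the mother's final measurement date (again at 1 week per
week) before averaging — averaging without a common time reference
would be incoherent. The projection also makes every prediction
date-shift equivariant: shifting all dates by k days leaves GA at the
last measurement unchanged and moves the EDD by exactly k days.

For the single-measure models used on a series, `first`, `mid`
(earlier central measurement for even counts) and `mean` selection
modes are provided, each projecting to the last measurement date the
same way.

## Fitting

Goodness of fit is the Pearson-style chi-squared
`Σ (obs−pred)²/max(pred, 0.5)` — a weighted least squares in which the
predicted mean proxies the variance; the 0.5-week floor prevents
division blow-ups at degenerate parameter vectors. Minimisation uses
the Nelder–Mead simplex with standard coefficients (`fatol 1e-6`,
`xatol 1e-4`, 5000-iteration cap; non-convergence is flagged, not
raised), which tolerates the non-differentiable 3b/3a switching rule.
Observation units: each (SFH, ultrasound-GA) pair for models 1–2; each
triple's prediction against the ultrasound GA at the triple's last
date for model 3 (per-triple rather than per-mother matching gives
many more observations and a better-conditioned 11-parameter search).
`Gmin`/`Gmax` are optimised on a continuous relaxation along with the
other nine parameters by default, and can be frozen via
`options={"freeze_bounds": True}` if the switching rule makes a
particular fit fragile.

The train/test protocol draws a mother-level random half (fraction
configurable, train size rounded half-up), fits on it and evaluates on
the remainder.

One estimator caveat, visible in the recovery simulations: because the
chi-squared weights depend on the fitted parameters, the estimator
carries a small O(noise²/pred) bias — with 2-week GA noise the linear
intercept recovers ≈ 0.1 week high while the slope is essentially
unbiased. This is a property of the prescribed objective, not of the
optimiser.

## Evaluation

Births are categorised premature (< 37 weeks), term (37 to < 42) and
post-term (≥ 42). The report assembles: category percentages (model
vs ultrasound); 2×2 classification tables for premature and post-term
(undefined ratios reported as missing, never 0); histograms of
predicted GA at birth (1-week bins) and of residuals (7-day bins); the
mean residual; and the percentage delivered within two weeks of the
predicted date (|residual| ≤ 14 days, closed bound). Residuals are
model EDD − ultrasound EDD in days, equivalent to GA differences at
delivery. 95% prediction intervals are empirical 2.5th/97.5th
percentiles of residuals grouped by measurement count (3, 4, …, 9,
≥ 10 pooled), with linear interpolation between order statistics
(nearest-rank available); empty groups are omitted with a warning.
The prematurity cutoff sweep re-thresholds the predicted GA at birth
over 37.0–39.0 weeks in 0.2-week steps against a fixed < 37-week
truth.

## Risk-factor adjustment

Each of the nine recognised mother-level factors (weight, height, BMI,
age, gravidity, parity, smoking, *P. falciparum* and *P. vivax* slide
positivity) is tested one at a time as a single additive, mean-centred
linear term on the model-3 prediction, its coefficient refit with the
base parameters held fixed (binary factors enter the same way, as
offsets). The comparison operates at the mother level — one
observation per mother (ultrasound GA at her last measurement date vs
her model-3 prediction) — because a mother's triples share her growth
curve and are strongly correlated; testing per triple would overstate
the evidence several-fold. Since the residual variance of GA
predictions (a few weeks²) is far smaller than the predicted mean
(≈ 38 weeks), the raw chi-squared difference is severely deflated as a
χ²₁ statistic; significance therefore uses the dispersion-scaled
difference `Δχ² / (χ²_with/(N−1))` referred to χ²₁ at α = 0.05 (the
quasi-likelihood correction). Both raw values and the scaled statistic
are reported. On simulated cohorts this test holds its size (≈ 5%
false positives on null covariates) and detects a 0.5-week-per-SD
true-GA offset with high power at 300 mothers.

## The synthetic cohort

The simulator emulates a serial-SFH antenatal programme, not any
particular dataset. Per mother it draws a latent saturating-
exponential height curve `H(g) = P(1−e^{−r(g−g0)})` (zero before the
onset `g0`) — deliberately a *different* family from the predictive
models, so fits to simulated cohorts are honest misspecified-model
exercises. Defaults: plateau `P` 35 ± 4 cm, rate `r` 0.105/week ± 20%,
onset `g0` 6 ± 1.5 weeks, measurement noise 1.5 cm, recorded heights
rounded to whole centimetres and floored at 1 cm. The heterogeneity
sds were calibrated once so that the cohort reproduces the ~10-week
(90th−10th percentile) GA spread at SFH 20 cm characteristic of real
serial-SFH data (achieved: ≈ 9–11 weeks at n = 2000 across seeds).

Visits start uniformly in weeks 8–14 (the anchor, an error-free
ultrasound at the first visit, is labelled CRL before 11 weeks and BPD
after), repeat every 28 days until 34 weeks and every 14 days
thereafter until delivery, capped at 16 measurements. The late-visit
interval is 14 rather than 7 days because a cohort already filtered by
the two-week spacing rule cannot contain weekly-measured series; this
keeps post-exclusion retention above 95%. Delivery GA is Normal(39.5,
1.5) truncated at the 42-week induction ceiling except for the 10% of
mothers drawn as induction refusers. Covariates are drawn with
realistic marginals but no effect on anything by default; an injected
effect (`covariate_effects`, weeks of true-GA offset per covariate SD)
shifts the mother's ultrasound GA relative to her height trajectory,
the confounding pattern the risk-factor adjustment is designed to
detect.

What passing tests on this cohort do **not** show: robustness to
observer error structure (inter-midwife biases), missed-visit
patterns, anchor error (an `anchor_noise_sd_weeks` knob exists,
default 0), or population differences in growth curves — a model
refit is expected before use on a new population.

## Numerical and design choices

- EDD rounding: nearest day, half-days forward (`floor(x+0.5)`).
- Chi-squared floor ε = 0.5 weeks.
- Percentile definition: linear interpolation (configurable).
- Equation-3b trust interval is closed at both ends.
- The packaged interval lookup used by the calculator is a synthetic-
  data template (regenerated from a 3000-mother simulated cohort with a
  wide 8–28-week enrolment window so every measurement-count group is
  populated); it exists to exercise the lookup path and must be
  replaced by the user's own evaluation output.
- The calculator refuses inputs violating the series rules (< 3
  measurements or < 14-day spacing) instead of warning: predictions
  outside the validated input regime are not emitted.
- Dates are ISO-8601 only; no locale-dependent parsing.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
recovery simulations use 20 replicates of 300–500 single-measurement
mothers; full-pipeline checks use simulated cohorts of 60–2000
mothers. These sizes give replicate standard errors comfortably inside
the asserted tolerances.

## Known limitations

- The three predictive models are population calibrations; the shipped
  defaults derive from one refugee/migrant population and will not
  transfer across populations without refitting.
- Model 3's prediction interval (± ~2–4 weeks at best) is comparable
  to the width of the premature band itself, so binary prematurity
  classification near the 37-week boundary is intrinsically unreliable
  whatever the cutoff; the cutoff sweep quantifies, but cannot remove,
  this.
- Nelder–Mead over the 11-parameter switching objective finds local
  minima; fits should be started from plausible values (the packaged
  defaults) and checked via the descent and convergence flags.
- No uncertainty quantification on fitted parameters beyond replicate
  spread.
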