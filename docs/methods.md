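# Methods

This note documents the health-economic model implemented by `trialcea`,
the assumptions and parameter defaults, and the numerical choices.

## Study design being modeled

A two-arm randomized trial (intervention vs. treatment as usual, labeled
`VR-CBT` and `TAU`) in a psychosis population, with assessments at
baseline, 3 months (posttreatment) and 6 months (follow-up). Each
assessment covers the preceding 3-month period. The evaluation takes a
societal perspective over the 6-month horizon; cumulative costs are the
sum of the posttreatment and follow-up periods (the baseline period
describes pre-randomization resource use and is available as a covariate).

## Costing

Each participant-period is costed as three cent-exact components
(half-up rounding to integer cents per line item, so components and the
societal total are additive to the cent):

- **Health care**: service contacts at fixed unit prices (hospital day
  EUR 255, psychiatrist visit EUR 96, nurse visit EUR 65, psychologist
  session EUR 94, VR-CBT therapy session EUR 116); medication as daily
  dose price x days plus pharmacist dispensing fees (EUR 6 per started
  30-day month, EUR 12 for the first month of a first-ever prescription);
  and a per-course VR equipment/licence cost of EUR 373.95 charged once
  to any participant who attended at least one VR-CBT session
  (optionally prorated by sessions attended / 16).
- **Travel**: 2 x 7 km per care visit at EUR 0.21/km (EUR 2.94 per
  return trip).
- **Productivity losses** (human capital approach): for participants in
  paid work, sick-leave days valued at contract hours/5 per day, plus any
  reduction of contract hours relative to baseline over the 13-week
  period, at gender-specific productivity rates (EUR 34.75/h male,
  EUR 26.36/h female).

All costs are indexed by a consumer-price factor (default 1.006).

## Outcomes

- **Responders**: a participant responds on an experience-sampling
  outcome (momentary paranoia, momentary anxiety, time spent with
  others) if their 6-month value improved by at least 20% relative to
  baseline (the boundary counts; direction is per-outcome). Zero
  baselines fall back to "any improvement".
- **QALYs**: the GPTS (paranoia) change score is standardized by the
  control arm's baseline SD, converted to a utility difference with a
  published factor of 0.1835 per SMD unit, and multiplied by the 0.5-year
  horizon. The same construction is applied per participant (own change /
  fixed control SD x 0.1835 x 0.5) so that the between-arm mean
  difference of the participant-level quantity equals the group-level
  mapping, which lets QALYs enter the joint regression and the bootstrap.

## Missing data

Monotone dropout is handled by multiple imputation by chained equations
with predictive mean matching (5 donors), one bootstrap-refit linear
model per imputation and per (period, variable), with baseline-only
predictors (arm, demographics, baseline safety behavior, and the
variable's own baseline value). Default m = 100 imputations. Estimates
are pooled by Rubin's rules (total variance W + (1 + 1/m)B).

## Estimation and inference

Incremental cost and effect are the treatment coefficients of a
two-equation SUR system (cost and effect on intercept + treatment +
optional baseline covariates), estimated by one-step feasible GLS;
binary responder outcomes use a linear probability model, so the effect
coefficient is the risk difference. With identical regressors in both
equations FGLS coincides with per-equation OLS, which the tests use as an
independent cross-check.

Uncertainty comes from a nonparametric bootstrap (default B = 5000),
resampling participants with replacement stratified by arm, refitting the
SUR per resample. Degenerate resamples are redrawn (up to 10B attempts).
With imputation, the bootstrap is either nested (B/m draws within each
completed dataset, concatenated) or run on a cell-wise stacked average.
The draws yield ICERs, CE-plane quadrant proportions (zero deltas count
as cost-increasing/effect-positive), and the CEAC: the fraction of draws
with strictly positive net monetary benefit lambda x dE - dC over a WTP
grid of EUR 0-100,000 in EUR 500 steps. Sensitivity scenarios re-run the
identical pipeline with extra baseline covariates (baseline safety
behavior, baseline admission costs, both).

## Synthetic trial generator

`generate_trial` produces trials whose defaults are calibrated to the
study conditions: 58 per arm; baseline GPTS means/SDs 85(34) vs. 77(31)
with a 16-point incremental improvement; experience-sampling outcomes on
their bounded scales; admission days as a zero-truncated negative
binomial reaching the per-arm period day totals; 16 VR-CBT sessions in
the intervention arm; 11.2% in paid work; monotone dropout of 8 then 12
participants. Bounded outcomes are drawn from truncated normals whose
underlying parameters are solved (scipy) so the configured targets are
the moments of the *truncated* law. `apply_missingness` imposes exact
monotone dropout counts, completely at random by default or weighted by
a baseline covariate. The generator is a testing device, not a
population model: covariates are sampled independently, and resource-use
intensity does not feed back into symptom trajectories.

## Numerical choices and test-time sizes

- Integer-cent arithmetic (floor(x*100 + 0.5)) for all cost lines.
- All RNG streams are `numpy.random.default_rng` seeded from explicit
  integers; derived seeds are drawn below 2^31.
- The test suite uses reduced sizes (m <= 10, B <= 1000, smaller n) to
  keep runtimes in seconds; defaults for real analyses remain m = 100,
  B = 5000.

## Limitations

No discounting (6-month horizon), no value-of-information analysis, no
probabilistic sensitivity analysis over unit prices. The QALY is a
mapped approximation from a symptom scale, not a measured utility. The
human-capital approach values lost work time at full productivity rates
and so yields higher losses than a friction-cost approach would.
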