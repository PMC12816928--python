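# Methods

## The measurement model

A CGM sensor worn on the upper arm reports interstitial glucose every 15
minutes. It is applied in the early afternoon (13:30 by default) and worn for
about five days, so the first and last calendar days are partial. The first
hours after insertion are physiologically unreliable (sensor warm-up) and are
discarded; the default trim is 3 h, configurable up to the more conservative
24 h some groups prefer.

Analysis is day-based: the trace is cut at local midnights into half-open
calendar-day windows [00:00, 24:00). The "midnight to 23:59" convention in
clinical descriptions is equivalent here because no grid sample can fall in
the open boundary minute. A complete day holds 96 samples; completeness is
the duplicate-free sample count divided by 96 (the fixed expected grid, not
the observed span), and a day is valid at completeness ≥ 0.80 — so 77
samples pass and 76 fail. Subjects need ≥ 2 valid days. Missing samples are
never imputed; days are filtered, not repaired.

## Episode detection and the four biomarkers

A hypoglycaemic episode is a maximal run of samples strictly below
70 mg/dL with at least two measurements in which every adjacent pair is at
most 30 minutes apart. Three readings of this rule were open and are
resolved as follows:

* *Strictness at the threshold*: a sample at exactly 70.0 mg/dL is not
  hypoglycaemic ("fell below" read literally).
* *Runs longer than two*: the 30-minute pairing window applies to every
  adjacent pair; the two-sample case is the stated minimum and is preserved.
  A data gap longer than 30 minutes therefore splits a run.
* *Integration*: the episode AUC is the trapezoidal integral of
  (70 − glucose) against real elapsed minutes over the episode's samples
  only, in mg/dL·min. The crossing between an in-range sample and the first
  low sample is not interpolated; this under-counts each episode by at most
  half a grid interval of deficit on each side, identically for all
  subjects, and keeps the statistic a pure function of the detected samples.

Per valid day: mean and minimum glycaemia over all samples (an isolated
sub-70 sample affects the minimum though it is no episode), CV as the n−1
sample SD over the mean, and the hypoglycaemic AUC as the sum over the day's
episodes (0 for a day without episodes — such days still contribute to the
subject mean). Episodes are detected within each day window, so an excursion
crossing midnight contributes to both adjacent days separately; this follows
from defining every biomarker per 24-h period. The subject-level biomarker
is the unweighted mean of the daily values across valid days.

The nocturnal variant restricts each day to [00:00, 06:00) on the clock
(no standard definition exists; the bounds are configurable, including
windows wrapping midnight), re-bases completeness on the 24 samples the
window can hold, and applies the same 80% validity and 2-day eligibility
rules.

## Cohort statistics

Spearman rank correlations (midranks for ties, asymptotic t p-values —
appropriate at cohort sizes in the hundreds, where exact permutation is
unnecessary) relate each biomarker to BMI and illness duration, with
pairwise deletion so each correlation uses every subject with both values.
OLS with intercept regresses each biomarker on BMI, illness duration and
EDI-2 total (complete cases, more than 5 required), reporting per-coefficient
β, SE, t and p, R², adjusted R² and the overall F-test. BMI severity uses
the DSM-5 anorexia bands — mild ≥ 17, moderate [16, 17), severe [15, 16),
extreme < 15 kg/m² — which partition the underweight range without gaps, and
a Kruskal–Wallis test across non-empty bands (identical values everywhere
yield H = 0, p = 1 by convention). No multiple-testing correction is applied.
Degenerate inputs are flagged, not fatal: zero-variance vectors give an
undefined correlation with a note, collinear designs skip that regression,
and the pipeline completes.

## The synthetic cohort

No clinical recordings are distributed, so validation uses a generator whose
structure is minimal but sufficient to produce realistic CVs (~0.13) and
sub-70 episodes. Covariates are independent truncated normals; defaults
describe underweight adult women (age 25 ± 6 y, BMI 16.2 ± 1.3 truncated
below 18.5 kg/m², illness duration 8 ± 6 y on [0.25, 30], EDI-2 110 ± 40).
Each trace is

```
glucose(t) = mu + circadian(t) + meals(t) + AR1(t) − dips(t),  floored at 40
mu         = a0 + a1·duration + a2·edi2 + delta,   delta ~ N(0, subject_sd)
```

with defaults: baseline a0 = 82 mg/dL, adaptation slope a1 = 0.35 mg/dL per
illness year, EDI-2 slope a2 = −0.02 mg/dL per point, between-subject
intercept SD 6 mg/dL; circadian amplitude 5 mg/dL (peak 14:00, trough
02:00); meals at 08:00, 12:30 and 19:30 adding 25 mg/dL decaying
exponentially with τ = 90 min; stationary AR(1) noise with marginal SD
8 mg/dL and coefficient 0.7 (≈ 25-min decorrelation, plausible for
interstitial dynamics); hypoglycaemic dips as 60-min half-sine depressions
of 25 mg/dL at 0.5/day; a 40 mg/dL floor (below the reporting range of
common sensors) preventing non-physiological values. Missingness combines
2% i.i.d. point dropout with 120-min block dropouts at 0.3/day. Wear time
defaults to exactly 5 days; a `wear_days_sd` knob adds per-subject
truncation for studies of ragged wear, off by default since no empirical
wear-time distribution is claimed. The subject random intercept is what
makes effect sizes meaningful: without it, any nonzero adaptation slope
would dominate the between-subject variance and correlations would be
near 1.

One seed drives everything; each subject's covariates, trace and missingness
come from that subject's own spawned substream, so cohorts are
bit-reproducible and subjects are order-independent.

**What the generator does not emulate**: true glucose–insulin dynamics,
vendor-specific sensor error and calibration drift, behavioural coupling
(meals skipped on bad days), covariate correlations (age, BMI, duration and
EDI-2 are sampled independently), or the empirical wear-truncation
distribution. Passing recovery tests therefore show that the pipeline's
inference is correct *given* this data-generating process, not that the
clinical effect sizes themselves are reproduced.

## Calibration and validation sizes

`calibrate_adaptation_slope` embeds a target population Spearman ρ between
illness duration and mean glycaemia. Because the slope enters the subject
mean additively, one cohort simulated at slope 0 gives means `m0`, and the
induced ρ of `m0 + slope·duration` is a deterministic, non-decreasing
function of the slope on those common random draws; bisection solves it to a
tolerance of 0.01 (calibration cohorts of 20 000 subjects keep the
Monte-Carlo error of the target near 0.007). Targets unreachable under the
configured variance budget raise a diagnostic error rather than returning a
boundary slope.

Validation sizes were chosen to keep the whole suite around a minute on one
CPU while leaving Monte-Carlo error well inside the asserted tolerances:
detector-vs-oracle and AUC properties on 1000 random traces; null
calibration of the Spearman test over 500 cohorts of n = 300 (rejection rate
0.05 ± 0.02 at α = 0.05); full-pipeline recovery of embedded ρ* ∈ {0.1,
0.25, 0.4} at n = 2000 subjects within ±0.05 (Spearman sampling SD at that n
is ≈ 0.022); and 95% CI coverage of the generating slope over 500 OLS
replicates at n = 300. The replicate loops use the generator's vectorised
subject-mean path — the identical generative model without per-trace
day-level QC — since day segmentation only adds a small attenuation that the
single full-pipeline recovery runs already cover.

## Known limitations

* The episode AUC is not interpolated at threshold crossings, so very short
  shallow episodes are weighted slightly less than a continuous-time
  definition would weight them.
* Completeness is judged against the fixed 96-sample grid; a sensor
  reporting off-grid timestamps is accepted (day assignment uses actual
  timestamps) but cannot exceed completeness 1 only by assumption, not by
  construction.
* Midnight-crossing excursions are split between days by design; a
  continuous-episode analysis would need a different day convention.
* The regression stage assumes linear covariate effects; no interaction or
  nonlinear terms are fitted.
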