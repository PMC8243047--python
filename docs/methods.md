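# Methods

## Cohort definition

The analysis population is the set of unplanned critical-care
admissions from a general ward with *new and sustained* physiological
derangement. Derangement is measured by NEWS; "sustained" means the
first observation scoring ≥ 7 (the emergency-response threshold) after
which no pre-admission observation falls below 5 (the urgent-review
threshold). The tolerance down to 5 admits natural fluctuation and
partial response to treatment without resetting the clock. Critical-care
admission ("the door") is timed by the first heart rate recorded on the
unit, which is charted promptly and avoids administrative timestamp
error. The Score-to-Door (STD) exposure is the trigger-to-door interval
in decimal hours.

Four exclusion steps run in a fixed order, and each patient is counted
exactly once, at the first step that removes them: (1) pathway —
admissions direct from the ED, with an intervening theatre visit, or
with no identifiable level-1 ward stay before critical care; (2) no
sustained trigger; (3) STD > 168 h; (4) missing analysis variables
(complete case). The ledger invariant `included + Σ exclusions = total`
is enforced at run time and property-tested.

Interval conventions. All windows are half-open: the pre-admission
interval excludes the door instant itself (an observation time-stamped
exactly at the door cannot break the sustained condition), the 168-hour
cap is inclusive, and out-of-hours is [Sat 00:00, Mon 00:00) plus
weekday [20:00, 24:00) and [00:00, 08:00), which integrates to exactly
108 of the week's 168 hours. A sub-floor observation appended before
the door can only move a trigger later or remove it, never earlier —
also property-tested.

When a patient has several critical-care admissions, the first one
reached from a ward defines the index episode; trigger search starts at
hospital admission. "Time to trigger" enters models in days.

## NEWS band tables

Band tables are declarative data: per parameter an ordered list of
half-open `[lower, upper)` intervals mapped to component scores
{0,1,2,3}, plus a consciousness map (any non-alert level scores 3) and
the supplemental-oxygen weight (2). Two versioned tables ship —
`news_2012` and `news2_scale1` (default); they share the numeric
thresholds, differing only in provenance and the consciousness scale's
naming, and both attain the scale maximum of 20. The SpO₂ scale for
hypercapnic respiratory failure is not implemented. Temperature is
compared at one-decimal precision; all other vitals are integers.
Out-of-range values (e.g. SpO₂ = 110) are rejected, never clamped:
silent clamping would corrupt cohort derivation. Table validation
checks the partition (no gaps/overlaps), the score range, and the
maximum total.

## Statistical models

* Descriptives: continuous variables as median [IQR] compared by
  Mann–Whitney U (exact for groups ≤ 8 without ties, otherwise normal
  approximation with tie correction); binary variables as count (%)
  compared by Fisher's exact test (two-sided, point-probability
  method). Variables constant across both groups report p = 1 with a
  note.
* Mortality (critical-care, hospital): stepwise logistic regression.
  Each candidate is screened in a single-predictor model at p < 0.2;
  survivors enter a multivariable model that always contains the STD
  exposure. The screen is re-run per outcome. Candidates that fail to
  fit (perfect separation, constant value) are dropped with a warning.
  Effects are odds ratios e^β. The intercept is always fitted and
  reported.
* Length of stay and STD determinants: OLS on the natural log of the
  strictly positive outcome, with an a-priori variable list (no
  screen); the LOS model is fitted on critical-care survivors only. A
  coefficient β is also reported as the percent change
  100·(e^β − 1) per unit. (Note |β|·100 is a common shorthand
  approximation; the exp-based transform is the default here, so
  β = −0.079 reads −7.6%, not −7.9%.)
* Confidence intervals: bias-corrected accelerated bootstrap,
  resampling patients with replacement (default B = 2,000, seeded). The
  bias correction z₀ comes from the bootstrap distribution; the
  acceleration a from per-observation empirical influence values
  (H⁻¹·score for the logistic MLE, (XᵀX)⁻¹xᵢeᵢ for OLS), equivalent to
  the jackknife skewness without n leave-one-out refits. With B = 0 the
  model falls back to analytic Wald intervals and labels itself so. The
  implementation is cross-checked in tests against an independent BCa
  (scipy's) on a smooth statistic. Wald p-values are reported; final
  significance is read at p < 0.05.
* Sensitivity: final models are refitted on a median-imputed version of
  the not-complete-case cohort and the significance calls compared
  term by term.
* Block summaries: 2-hour half-open blocks of STD clipped at 48 h, with
  per-block mean, n, and normal-approximation 95% CI (omitted for
  single-member blocks).

## Synthetic ward-EHR generator

The generator emulates the raw tables a hospital data warehouse would
supply, under the study conditions: lognormal admission latency with
median 6.3 h and σ = 0.732 (giving IQR 3.8–10.2 h); lognormal onset of
deterioration with median 3.3 days from hospital admission; triggering
NEWS drawn from {7: .40, 8: .25, 9: .20, 10: .08, 11: .05, 12: .02}
(median 8 [7–9]); archetype mix defaulting to 50% ED-direct, 39%
never-sustained, 1% beyond the 7-day cap (chosen once; the source
flowchart does not separate this group) and the remainder included;
covariate marginals (age ~ N(65, 16²) clipped, Charlson median 10,
frailty zero-inflated, SOFA median 5, ventilation 42.7%, sepsis 35.6%)
matching the published cohort's descriptives. Critical-care death is
Bernoulli on a logistic predictor with per-hour log-odds ln(1.02) by
default; length of stay is lognormal around a log-linear predictor with
0.012 per hour. Observation frequency is protocolised: ~6-hourly while
stable, hourly after deterioration onset.

Vitals are constructed *score-first*: a target NEWS total is drawn,
decomposed randomly into per-parameter component scores (weighted
toward the clinically typical direction — hypotension over hypertensive
crisis, tachycardia over bradycardia), and each component realised by a
uniform draw inside a band carrying that score. This was chosen over a
drift-plus-noise vitals model because it makes the generator's
guarantees provable: every "included" patient is detected by the
sustained-trigger rule with exactly the generated trigger score and
exposure, and every violator fails at the intended ledger step — a
round trip the test suite asserts exactly. The cost is realism: the
generator does not produce circadian rhythms, treatment responses,
autocorrelated vitals, informative missingness, or charting gaps, and
its out-of-hours fraction of triggers is the clock-uniform 64%, not the
~54% seen in real charting. Passing tests therefore demonstrate the
pipeline's correctness and calibration on data satisfying the stated
models, not robustness to real-EHR artefacts.

Missingness is injected completely at random into Charlson, frailty and
SOFA only, to exercise both the complete-case and imputation paths.
Determinism: all draws flow from `numpy.random.default_rng` seeded per
table from the configured seed; identical configs give byte-identical
CSVs.

## Test problem sizes and numerical choices

Oracle-equivalence suites use 10,000 random observations (scorer vs an
independently coded linear-search chart) and ≥ 1,000 random score
sequences (trigger detector vs an O(n²) scan). Parameter recovery runs
the full raw-tables-to-models pipeline on 20 replicates of n = 5,000
included patients with B = 200 bootstrap resamples per replicate,
thinning the uninformative pre-deterioration observations to two per
patient; recovery is judged by |bias| < 2 Monte-Carlo SE and ≥ 16/20
BCa coverage of the generating coefficient. Screen calibration uses
2,000 null replicates at n = 2,000 and expects retention within ±0.03
of the 0.2 screening level. Logistic fits use Newton's method with
warm starts inside the bootstrap; fits with |β| > 50 or failed
convergence raise rather than return silent coefficients.

## Known limitations

Single hospital stay per patient (no readmission chains); SOFA,
Charlson and frailty are supplied covariates, never computed from raw
data; no survival-time modelling; the generator's limitations above.
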