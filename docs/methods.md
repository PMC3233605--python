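# Methods

This note records the conventions, parameter choices and known limitations of
the `rxtrends` pipeline and its synthetic-data generator.

## Interval conventions

All internal intervals are half-open `[start, end)` and all durations are
exact integer day counts; person-days of an interval are `end − start`.
Dates in input/output CSVs are inclusive calendar dates (ISO-8601); an
inclusive end date such as a registration end or the study end 2009-12-31
becomes the exclusive bound *date + 1 day* on read. This removes every
off-by-one ambiguity from interval unions and calendar-year slicing while
keeping files human-readable.

When a source supplies only a year of birth, the birth date is imputed as
July 1 of that year (`birth_imputation_monthday`, configurable). Mid-year
imputation bounds the age error by half a year in either direction.

## Cohort definitions

* **Eligible**: ≥ 1 bipolar diagnosis code dated inside the study window,
  no epilepsy code at *any* date (the pharmacological overlap between
  anticonvulsant mood stabilisation and epilepsy treatment contaminates
  exposure regardless of when epilepsy was recorded), and age 18 reached
  before follow-up ends.
* **Follow-up** starts at the latest of study start, registration start,
  practice data-quality date and 18th birthday; it ends at the earlier of
  study end and registration end. By default follow-up does *not* start at
  the first bipolar diagnosis: the cohort is read as prevalent, with
  person-time independent of diagnosis date. `follow_up_from_diagnosis=True`
  switches to the incident-style alternative.
* **Treated**: ≥ `min_prescriptions_treated` (default 2) classified
  psychotropic scripts inside follow-up — two scripts signal an intention to
  treat plus initial concordance, distinguishing treatment from a one-off
  trial prescription.
* Patients with a missing Townsend quintile remain in all overall analyses
  and drop out of deprivation-stratified tables only.
* Unknown drug codes classify to an explicit `unclassified` marker, are
  excluded from every analysis, and are counted in the attrition log; they
  are never silently dropped.

## Treatment sessions

A session is a maximal period of continuous prescribing of one hierarchy
unit. Two conventions matter:

* **Gap threshold** `gap_days = 91` (≈ 13 weeks). The field convention is
  "three months"; a fixed day count keeps the rule auditable and
  configurable. The gap is measured between consecutive prescription *issue*
  dates, not between coverage end and the next issue.
* **Forward coverage** `coverage_days = 28`: a script covers the modal UK
  repeat-prescription length, so a session ends 28 days after its last
  script (truncated at follow-up end). `coverage_days = 0` reproduces a
  strict last-script-date convention, at the cost of zero-length
  single-script sessions.

Same-day duplicate scripts of a unit collapse for the continuity test (they
carry no extra temporal information) but still count toward
`n_prescriptions` and the ≥ 2-scripts rules. Scripts issued before the
follow-up window are ignored entirely — no look-back bridging — mirroring
the observable-time-only reading of primary-care data; hospital-prescribing
gaps are likewise not bridged (see Limitations).

Because between-session gaps (≥ 91 days) always exceed forward coverage
(28 days), sessions of one unit are pairwise disjoint and the greedy
partition is equivalent to the day-grid definition "a day is covered iff it
is within 28 days after a script or lies between two scripts < 91 days
apart". The test suite asserts this equivalence against a brute-force
day-grid oracle on randomized instances.

## Person-time estimation

The primary estimand is the **pooled** proportion: summed covered days over
summed follow-up days, per year × stratum × unit. Pooled person-time weights
patients by their observable time and is the estimand that pairs naturally
with reported total person-years; a per-patient-mean variant
(`proportion_method="patient_mean"`) is available as a sensitivity analysis.
The denominator is all eligible members' follow-up — treated and untreated —
since "proportion of time in treatment" is a population statement;
`denominator="treated_only"` gives the restricted variant.

Age-band membership is assigned per analysis year at July 1. Person-time of
patients outside all configured bands (e.g. 76+) stays in the overall
analysis and is reported under an `outside-bands` label, so band strata plus
the extra label always partition the overall person-time exactly (an
invariant the tests assert).

Percentages, differences and ratios in report tables are rounded half-up to
one decimal place *at the reporting edge only*; endpoint differences and
ratios are recomputed from the rounded endpoint percentages so that printed
cells are mutually consistent. A ratio with a zero baseline is reported as
undefined (NaN). Mean annual change is the endpoint slope
`(last − first) / (year span)`.

## Co-prescribing

"On a drug in year *y*" means ≥ 2 scripts of that generic in *y* — the same
intention-to-treat threshold as the treated flag, applied per drug.
Multi-drug status counts distinct *generic* drugs (two different FGAs
count; `multi_drug_level="class"` gives the class-level variant). Pair
combinations require both components to qualify in the same calendar year;
no temporal overlap of sessions is demanded, because the counts are
prescription-based. The time-share analysis is the asymmetric, time-based
complement: it requires ≥ 1 day of concurrent sessions of both components,
then averages each component's share of follow-up across qualifying
patients.

## Synthetic-data generator

The generator emulates the record structure the pipeline consumes:

* registration windows with entry years 1985–2007, exponential exit
  (hazard 0.04/yr), and a practice data-quality date that truncates early
  follow-up;
* demographics: 61.4% female, age at study start ~ N(44.5, 15.2) years,
  Townsend quintiles near-uniform with 3% missing — the magnitudes reported
  for treated UK primary-care bipolar cohorts;
* per-drug prescribing as a blocked renewal process: in any year a patient
  is not in (or blocked after) a session, a calendar-year hazard — modulated
  by sex and age — may start one; session lengths are log-normal, refill
  intervals truncated-normal with mean 28 d capped strictly below the gap
  threshold, and post-session blocks are the gap threshold plus an
  exponential excess, so within-session gaps are always < 91 d and
  between-session gaps ≥ 91 d;
* lithium→antipsychotic coupling (probability 0.35 that a lithium session
  start triggers a concurrent antipsychotic start) to create realistic
  co-prescribing;
* deliberate contamination: 3% of patients with out-of-window diagnoses
  only, 2% epileptic, 10% never prescribed, 1% junk-code scripts (injected
  as *extra* rows so the classified stream is unchanged), all exercising
  exclusion paths.

The shipped preset (`uk_prescribing_preset()`, n = 3,000) encodes the
qualitative late-1990s/2000s UK regime: SGA hazards zero before 1996 then
rising steeply, valproate zero in 1995 then rising, lithium flat with a
strong positive age gradient, FGAs declining. First-year hazards of
established drugs are boosted because the simulated cohort opens with no
prescribing history; the boost stands in for prevalent users whose ongoing
treatment becomes visible when the window opens.

**Ground truth is empirical, not analytic**: after generation, an
independent day-grid implementation marks covered person-days per hierarchy
unit over each truth-eligible patient's window, and yearly treated/
multi-drug counts are tallied per patient in plain Python. Recovery tests
against the pipeline are therefore *exact* (zero discrepancy at matched
conventions) rather than Monte-Carlo-noisy; the estimator-consistency
property is realized as this exactness plus a closed-form check on a
designed configuration (fixed 109-day lithium sessions each year, giving a
known coverage fraction 109/365). What passing these tests shows is that the
pipeline computes its estimand correctly on data with the configured
structure; it cannot show that real prescribing follows that structure —
dose, titration, hospital prescribing, practice-level clustering and
code-vocabulary noise are all absent from the generator.

## Problem sizes

The default test suite uses replicates of 40–250 patients for structural
checks and one 3,000-patient preset replicate for the recovery checks;
`scripts/acceptance.py` uses deterministic fixtures of up to 3,870 patients
plus the 3,000-patient preset. These sizes give exact structural assertions
and sub-percent Monte-Carlo noise where sampling enters.

## Known limitations

* Gaps bridged by hospital prescribing (e.g. inpatient stays) are not
  corrected for, so treatment duration may be underestimated; no correction
  is attempted, matching standard practice for primary-care dispensing data.
* No dose, quantity or days-supply modelling; coverage is a fixed 28-day
  convention per script.
* Bipolar I and II cannot be distinguished from diagnosis codes alone.
* The endpoint trend table inherits the instability of a small first-year
  denominator; the mean-annual-change statistic uses endpoints only and is
  not a regression slope.
* Codelist construction (Read-code / product-code curation) is out of scope;
  the pipeline consumes finished codelists.
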