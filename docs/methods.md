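# Methods

This note documents the models, conventions and design choices behind
`chcincidence`: what each estimator assumes, what the synthetic generator
does and does not emulate, and where genuinely open decisions were settled.

## Phenotype ascertainment

A chronic health condition (CHC) is any diagnosis on a curated ICD-10 code
list, each code mapped to one of nine body-system subtype groups
(cancer/blood; cardiovascular; respiratory; neurological; mental
health/behavioural; metabolic and other — covering metabolic, endocrine,
digestive, renal and genitourinary conditions; musculoskeletal/skin; chronic
infections; non-specific). Ascertainment scans all diagnostic positions of
every inpatient episode (up to 20 codes), including the birth episode, and
keeps the first instance per child overall and per subtype. Diagnosis
position is ignored: a code in a secondary position counts the same as a
primary diagnosis.

**Matching convention.** ICD-10 codes are normalized to uppercase, dot
stripped, at most four characters. A record code matches a list entry if
they are equal, or if the record code's three-character truncation equals a
three-character list entry (the standard phenotype-list convention for lists
that mix granularities). When both a four-character entry and a
three-character prefix entry match, the more specific four-character entry's
subtype wins. A three-character record code never matches a four-character
entry: the record is less specific than the list and the match cannot be
certified. The CSV reader accepts single codes only, not code ranges; a
range-style list must be expanded before loading.

## Closed-cohort estimation

Follow-up runs in integer days from birth; ages in years are
`floor(days / 365.25)`, making all age arithmetic reproducible. The endpoint
per child is the earliest of: first matching CHC record; death; first
hospital contact with a non-England domicile (censoring at that episode's
start date); the 16th birthday (day 5 844); the administrative end of data
(31 August 2019 by default). Two tie-break conventions matter:

- **Event vs same-day censoring: the event wins.** Birth-episode conditions
  occur at day 0, the same day a child could in principle be censored;
  counting them requires this order.
- **The 16th birthday is exclusive.** Censoring occurs at day 5 844 and an
  event on that exact day is out of window, so "by age 16" always means
  strictly before the 16th birthday. The same strict-inequality rule defines
  "by age a" at every reporting age and every multimorbidity landmark.

The cumulative incidence is one minus the Kaplan–Meier product-limit
estimate, with same-time censorings evaluated after events (they remain in
the risk set at their own censoring time). The Aalen–Johansen estimator
re-treats death as a competing event: the cause-specific incidence
accumulates `S(t−) · d_CHC/n` where `S` is overall event-free survival. With
no deaths the two coincide exactly; with deaths the competing-risk curve is
bounded above by the censoring-based one. Both estimators are implemented in
the package rather than delegated, so the test suite can hold them against
an exhaustive exact-arithmetic risk-set oracle and against an independent
library implementation; Greenwood-type standard errors are computed as a
diagnostic but carry no downstream weight.

**Eligibility variants.** Every variant requires a recorded live birth.
"Subsequent hospital activity" means any admitted-patient, outpatient or A&E
contact strictly after the birth day; school (NPD) evidence means any
enrolment or examination record. The main analysis requires activity before
16 and/or a school link; the seven sensitivity variants require,
respectively: nothing further; activity before 5; activity before 16; a
school link; activity before 5 plus a school link; activity before 5 plus
activity between 5 and 16; and all three. The variants are partially nested
(s7 ⊆ s6 ⊆ s2 ⊆ s1, s7 ⊆ s5 ⊆ s4, main ⊇ s3 ∪ s4), which the tests verify
exhaustively.

**Cohort pairing and disclosure control.** Subtype-specific estimates pool
adjacent cohort pairs — re-estimating on the pooled follow-ups, never
averaging curves — with horizons of 16, 14, 12, 10 and 8 years for the five
pairs, each pair's horizon being the shorter member's maximum attainable
age. Reported tables mask cells whose within-year event count falls below a
configurable threshold (default 10, a typical administrative-data disclosure
rule) and flag a subtype as not reportable when its total event count is
below the threshold; suppression never feeds back into estimation.
Records dated after a child's death are rejected at assembly with a
data-quality error rather than silently repaired.

## Open-cohort estimation

Open cohorts are defined by financial year of birth (1 April – 31 March),
include immigrants, and take an external mid-year population series as the
denominator. For each age `a`: the denominator is the population estimate
minus the cumulative number of incident cases *before* `a`; the hazard is
`cases(a) / denom(a)`; and the cumulative incidence is `1 − exp(−IH(a))`
with `IH` the integrated hazard. Cases incident at the current age are not
discounted, because a child becoming a case mid-year contributed risk time
during that year; the alternative convention (discounting through age `a`)
is available behind the `include_current_age` flag. A non-positive
discounted denominator, or a case count exceeding it, raises an error naming
the age — these indicate incompatible numerator/denominator sources, not a
recoverable state. Population inputs are treated as exact point estimates
(no sampling-error term), and the mid-year count is used directly as the
person-time denominator without part-year exposure adjustment. Later cohorts
have shorter observable age ranges, derived from the cohort label and the
configured end of data.

The two designs estimate the same quantity under no migration, and the test
suite checks they agree within Monte-Carlo tolerance there; under unmeasured
emigration and immigration they bracket the truth from below and near it,
respectively, which is the package's central validation scenario.

## Multimorbidity

Multimorbidity is the number of *distinct body-system subtypes* ever
recorded per child before a landmark birthday (5, 11, 16), and the reported
proportion is `n(≥2 subtypes) / n(≥1 subtype)`. Two caveats are inherent to
the measure: multiple conditions within one subtype are invisible (the
count is a lower bound on condition-level multimorbidity), and the ratio is
not mathematically monotone in landmark age — newly affected single-subtype
children enter the denominator — even though per-child counts and both
tallies are; at population scale under realistic hazards it rises with age,
and the tests assert monotonicity only there. Chronic infections count
toward the subtype tally by default even where their incidence curve is
suppressed from reporting (the suppression is presentational); a toggle
excludes them. Multimorbidity denominators are restricted to the
main-analysis eligible population.

## Synthetic data generator

The generator emulates the statistical structure the estimators assume, not
the content of real hospital data. Per child, each subtype onset, death and
emigration is an independent competing process with piecewise-constant
yearly hazards over ages 0–15, sampled by inverse transform over the
cumulative hazard; the event day is uniform within the sampled year of age.
This makes the net cumulative incidence at whole ages exactly
`1 − exp(−Σ hazards)`, the ground truth for parameter-recovery tests.
Additional structure:

- every born child has a birth episode at day 0 (carrying any day-0 CHC
  codes); each CHC onset generates an inpatient episode carrying a random
  code of its subtype;
- a background (non-CHC) admission process plus outpatient and A&E contact
  processes provide the activity that eligibility variants require; a
  configurable multiplier raises the background admission rate for children
  with any CHC, switching on activity-correlated selection;
- emigrants cease all records at their emigration day, optionally leaving
  one final episode with a non-England domicile (probability 0.3 by
  default — most departures are invisible, the central bias mechanism);
- immigrants have no birth record, arrive at a configured age, and acquire
  hazards only from arrival (conditions acquired abroad are invisible,
  mimicking left truncation);
- linkage failure (default 5%) removes all of a born child's post-birth
  records; school enrolment (default 97%) generates yearly records from age
  4 while the child is present.

**Default study conditions.** Ten cohorts of 20 000 births (scaled down from
~600 000 real births per year); subtype hazards with an infancy excess for
congenital/perinatal-flavoured groups and a late rise for mental health,
summing to an any-CHC cumulative incidence of ~26% by 16; infant mortality
0.4% then 0.02%/year; emigration 0.5%/year. Migration and linkage rates
have no published ground truth, so these are demonstration values chosen
once for plausibility, not calibration. Not emulated: realistic ICD-10 code
frequencies, seasonality, within-year hazard shape, between-subtype
correlation (multimorbidity arises from independent hazards only — a known
limitation), geography below country level, and the mechanics of the
linkage algorithm itself (only its outcome, link success or failure, is
simulated). Passing tests therefore demonstrate estimator correctness under
the stated stochastic structure, not fidelity to real hospital data.

## Validation scenarios and problem sizes

The canonical scenarios live in `chcincidence.scenarios` and are used by
both the test suite and `scripts/acceptance.py`: parameter recovery and
multimorbidity use 50 000-child cohorts (Monte-Carlo standard error well
under the 1.5-percentage-point and 2-point tolerances asserted), the
eligibility-variant sweep uses 30 000, and the competing-risk comparison
20 000 and 10 000 — sizes chosen so each scenario runs in seconds on one
CPU while keeping sampling noise an order of magnitude inside the
tolerances. The exhaustive product-limit oracle enumerates all 3 002
multisets of up to eight follow-ups over times {1, 2, 3} and
event/censored status in exact rational arithmetic; since the estimator is
order-invariant (asserted separately), multisets cover all distinct inputs.

## Numerical and interface conventions

- Table percentages round half-up to one decimal (`Decimal`-based exact
  rational division before rounding), the convention that reproduces
  published cohort linkage tables from their printed counts.
- Curves are right-continuous step functions; whole-year reporting takes the
  value at the last day strictly before each birthday.
- All randomness flows from a single integer seed through one generator;
  identical configuration and seed give byte-identical output files.
- Tabular interfaces are plain CSV: code lists as `code,description,group`;
  episodes with `diag_01…diag_20`; populations as `cohort,age,population`;
  curve outputs as tidy tables with one row per cohort/variant/subtype/age.
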