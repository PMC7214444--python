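# Methods

## Problem and design

Published trial reports rarely release patient-level data; what they do
publish is the baseline-characteristics table — per-arm counts, means and
occasionally medians, sometimes with a trial-level standard deviation per
continuous row. `trialgap` compares an observational cohort against that
table. Two cohorts are built per trial from the same patient database: an
*indication-only* cohort (everyone with the drug's indication) and an
*indication-plus-criteria* cohort (the subset additionally meeting every
encoded eligibility criterion). Comparing both against the pooled trial
values shows whether the eligibility criteria move the real-world
population toward the trial or away from it.

## Data model

Persons carry birth year, gender/race/ethnicity concepts (explicit
Unknown is a first-class category, because the source tables report
Unknown rows) and a single observation window. Events are dated records
in five domains; only measurements carry values. Concepts are opaque
string identifiers in a packaged toy vocabulary with is-a edges (a DAG;
multi-parent nodes such as NSTEMI under both acute-coronary-syndrome and
myocardial-infarction are allowed). Dates have day resolution and every
temporal window is a closed interval in days; the index day belongs to
both the "before" and "after" side of a window.

## Cohort construction

A cohort definition is an indication criterion plus an ordered,
conjunctive list of eligibility criteria. The index date is the earliest
qualifying indication event — the common observational convention; the
rule is a single place in the code and could be swapped. Criterion kinds:
event presence/absence over a concept-set and window, measurement
thresholds, age range at index (index year minus birth year), demographic
equality, and an explicit `unoperationalizable` marker for soft criteria
(clinician-judgment rules), which the engine skips with a logged warning
rather than pretending to evaluate.

Measurement criteria with no in-window value evaluate **false** (the
patient is excluded), mirroring a screening visit where the lab must
exist; a "missing passes" policy would be a one-line change and is
deliberately not the default. When several in-window values exist, the
one closest to and not after the index date wins; if only post-index
values are in the window, the earliest is taken; remaining ties resolve
by record order. The baseline summariser uses the identical selection
rule, so criteria and summaries never disagree about "the" baseline
value.

Two evaluation paths exist by design: a vectorised pandas path used in
production and a per-person, per-event scan (`evaluate_criterion`) kept
as a reference; the tests additionally hold both against a third,
independent brute-force evaluator written inside the test suite.

## Pooling and the discrepancy statistic

Discrete rows: counts are summed across the two arms and divided by the
combined n. Continuous rows: arm means are averaged with weights
proportional to arm size. Median-reported rows (the PROVE-IT lipids) are
pooled by the same weighted average of arm medians; an average of
medians is not a median, so the result carries `value_kind =
"median_average"` as a caveat. Display rounding follows each table's
printed precision; internal values keep full precision.

Discrete discrepancy: `(cohort% − pooled%)/100`, rounded to three
decimals for display. Continuous discrepancy: a standardized mean
difference whose default denominator is the symmetric two-sample form
√((σ²_RCT + s²_cohort)/2). The trial-σ-only form is demonstrably
inconsistent with the published continuous cells (the age row's printed
−0.260 would require −0.344 under σ_RCT alone), while back-solving the
symmetric form yields a plausible cohort SD (≈7.7 years for age); since
the cohort SDs were never printed, continuous cells are not treated as
reproducible and the denominator stays configurable (`pooled`, `rct`,
`cohort`). When only one scale is available (median rows with no σ
column) the available one is used.

Significance flags are a **reconstruction**: the source analysis printed
p-values without naming a test. The package uses a two-sided one-sample
z-test (scale σ_RCT/√n) for continuous rows and a one-proportion z-test
against the pooled proportion for discrete rows, and labels every output
`reconstructed_*`. Degenerate inputs (NED, n < 2, no positive scale)
yield an explicit undefined marker, never a number.

## Table transcriptions and their audit

The four trials' baseline tables ship as row-oriented JSON: per-arm
values, the σ column where printed, the printed pooled cell kept
verbatim, and both printed cohort columns with their Δ cells. A
transcription-time audit recomputes every derivable cell and freezes a
flag per printed Δ cell: `exact` (recomputes to three decimals), `edge`
(off by exactly one final-digit unit, explainable by display rounding of
the printed cohort percent), or `inconsistent` (the printed inputs
contradict the printed cell — source-table misprints such as the
PROVE-IT race rows). Golden tests assert exact cells at three decimals,
edge cells within 0.001, and skip misprinted cells; two pooled cells are
likewise flagged non-derivable from their printed arm values. Of 156
printed discrete Δ cells, 130 are exact, 7 edge and 19 inconsistent.

## Synthetic population generator

The generator emulates the marginal structure of each trial's printed
indication-only column; it does **not** invent joint structure — all
characteristics are independent per person unless the optional Gaussian
copula hook is configured, and the packaged configs leave it off because
no correlations were published.

Provenance rules for the packaged emulation configs, applied at build
time from the transcription (no numbers are duplicated into the maps):

* category probabilities (gender, race) = printed percents / 100,
  normalised; where a printed column does not sum to 100 % (the
  ACCOMPLISH race column sums to 96.6 %) the shortfall goes to the
  declared remainder category (Unknown), which is then excluded from
  recovery checks;
* event prevalences = printed percents / 100; each row names the concept
  emitted (often a descendant of the concept the summariser queries, so
  the hierarchy is exercised end to end);
* measurement means = printed values; SDs default to the table's σ
  column. Where no σ exists a plausible adult value is chosen once and
  recorded in the map. Where a dichotomised companion row exists (HbA1c
  < 8 / ≥ 8 / Unknown) the cohort SD is instead back-solved so that
  P(X ≥ bound | recorded) matches the printed fraction under normality;
* recording probabilities = 1 − (printed Unknown fraction) where the
  table has an Unknown row, 0.97 otherwise, and 0 for rows the table
  marks NED (waist circumference, eGFR, urinary albumin:creatinine);
* age targets the integer age at index: the continuous draw is shifted
  by +0.5 and floored, so the integer-age mean matches the configured
  mean and threshold rows are exact. ACCOMPLISH prints no age mean, only
  P(age ≥ 65) and P(age ≥ 70); location and scale are solved exactly
  from those two exceedance probabilities;
* right-skewed labs whose printed σ is large relative to the mean
  (RENAAL triglycerides, ACCOMPLISH glucose) use a moment-matched
  lognormal — a truncated normal cannot carry σ > mean without visibly
  shifting the mean. Normal-family truncation bounds are kept at |z| ≳
  2.8 from the mean for the same reason;
* "years since diagnosis" is drawn from an exponential with the printed
  mean (positive support, realistic skew; a truncated normal at the
  printed σ would inflate the mean), realised as a backdated
  first-diagnosis event;
* the PROVE-IT index event draws its subtype (unstable angina / NSTEMI /
  STEMI) from the printed proportions at the index date itself;
* the ACCOMPLISH previous-antihypertensive-treatment ordinal rows have
  no published per-class data; drug classes are emitted independently
  (beta blockers at their printed prevalence, the other four classes at
  0.0346 each so that ~75 % of persons carry no class) and the counts
  emerge from distinct-class counting. These rows are a documented guess
  and are excluded from recovery checks, as are cohort min/max rows
  (extreme-value statistics the truncation bounds do not emulate; the
  published figure likewise drops them as implausible).

Temporal layout: one shared observation window (1995-01-01 to
2019-12-31 — long enough that backdated first-diagnosis events are
almost never clipped), index dates uniform over 2012-01-01 to
2019-06-30, condition/drug events 1-1825 days before index (post-index
placement available, used for post-index PCI), measurements 0-365 days
before index. Persons without the indication receive the same event mix
at uniform dates so the database is not empty outside the cohorts.

Determinism: a single `numpy` generator seeded per run drives every
draw in a fixed order; written CSV tables are byte-identical across runs
for the same (config, seed).

## Problem sizes used by tests and the acceptance script

Population sizes in the packaged configs are the printed indication-only
n divided by the chosen indication prevalence (0.4-0.6), e.g. 9,545
persons for RENAAL and 61,423 for ACCOMPLISH. The acceptance checks run
one full-size generation per trial plus twenty reduced-size (n = 4,000)
seeds for prevalence-coverage checks; unit and property tests use toy
databases of 40-200 persons. Recovery tolerances are 4-standard-error
bands (binomial for percents, with a small-count cushion of two persons;
σ/√n for means, ×1.2533 for medians).

## What passing tests do and do not show

The generator reproduces marginals under independence; it does not model
care patterns, visit structure, disease progression, or the correlation
between characteristics that real populations certainly have. Passing
the recovery checks therefore shows the pipeline is correct and
calibrated, not that real-world cohorts would behave like the synthetic
ones. Cohort sizes after criteria are not emulated (the real
with-criteria cohorts reflect the full published criteria lists; the
packaged definitions encode a representative operationalizable subset
per trial). The with-criteria columns of the tables are likewise not
generation targets — the synthetic with-criteria cohort is whatever the
encoded criteria select.

## Known limitations

* Criteria are conjunctive only; at-least-k-of groups are out of scope.
* One observation window per person; no visit-level structure.
* The eGFR row's "NED, biased reporting" marker is represented but no
  bias-detection logic is attempted (none was described).
* The attrition log has no published ground truth (the source reports
  final cohort sizes only); it is an artifact feature.
* Declarative documents (population configs, cohort definitions,
  characteristic specs) are validated by their pydantic models, which
  are the published schemas (`model_json_schema()` exports JSON Schema).
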