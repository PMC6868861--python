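# Methods

## The phenotyping model

`ckdcohort` implements a deterministic, rule-based computable phenotype
over per-patient event streams (labs, vitals, diagnosis codes,
medication orders). Two nested tiers are computed:

1. **Repository membership** — a disjunction of single-event predicates.
   It is intentionally permissive: one out-of-range value, one relevant
   diagnosis code, or one anti-hyperglycemic prescription suffices. This
   tier exists to bound the candidate population cheaply.
2. **Registry condition flags** — per-condition rules built from
   repeated measurements with minimum (and for glucose, maximum)
   temporal separation, diagnosis-code counts stratified by encounter
   setting, and medication evidence. Registry rules are evaluated only
   for repository members. Because every strict trigger implies a
   permissive trigger (HbA1c ≥ 6.5 ⊂ ≥ 5.7; glucose ≥ 200 ⊂ ≥ 140;
   fasting ≥ 126 ⊂ ≥ 100; an eGFR pair ⊂ a single low eGFR; a BP pair ⊂
   a single high reading; any condition code ⊂ any condition code; a DM
   medication ⊂ an anti-hyperglycemic prescription), registry ⊆
   repository holds for every input, and the test suite asserts it as an
   invariant rather than assuming it.

The engine is purely functional in the event streams: shuffling input
row order never changes a verdict, and adding evidence never revokes a
flag, with one documented exception — a PCOS diagnosis can clear DM when
the *only* DM evidence is metformin (see below). Because computed eGFR
supersedes a source-system eGFR reported on the same date, adding a
creatinine measurement on such a date can in principle replace a
qualifying value; the monotonicity property is stated over lab, vital,
diagnosis and medication additions that do not retroactively reinterpret
an existing observation.

### Assumptions

* Dates are date-only; all gap arithmetic is in whole days, and "at
  least N apart" is inclusive (gap ≥ N). "No more than 2 years" is
  730 days, ignoring leap days. These conventions are simple, testable,
  and configurable where sources disagree (see below).
* Fasting vs random glucose is decided at ingest from an explicit
  fasting flag and never inferred downstream. Random and fasting
  glucoses are never pooled into one qualifying pair, and both members
  of a pair must satisfy the same band — a DM-range and a
  prediabetes-range value never combine.
* Diagnosis-code matching is prefix-based on normalized (dotless,
  uppercase) codes, the standard way of handling the ICD hierarchy. The
  shipped prefix lists (CKD N18/585; HTN I10–I15/401–405; DM
  E08–E13/250; prediabetes R73.03/790.29; PCOS E28.2/256.4) are
  configuration, not clinical truth: a deployment substitutes its own
  curated sets.
* "Two outpatient DM codes" requires two distinct encounter dates; two
  codes recorded on the same day are treated as one encounter.

## eGFR estimation

Adults (≥ 18 completed years at the draw) use the 2009 CKD-EPI
creatinine equation; constants (scale 141, κ 0.7/0.9, α −0.329/−0.411,
exponent −1.209, age base 0.993, female multiplier 1.018) live in
configuration. The equation's racial coefficient (1.159) is contested
and **off by default**; enabling it is a single config switch and the
active mode is written to the run manifest so no run is ambiguous.
Children use bedside Schwartz (k = 0.413) with the nearest height within
a configurable lookback (default 365 days; ties prefer the earlier
measurement). A pediatric creatinine with no usable height yields no
eGFR and a logged skip — dispatch is a partition: every creatinine
routes to exactly one equation or one logged skip.

When a source system supplies a precomputed eGFR on a date that also has
a computed value, the computed value wins and a discordance message is
logged when they differ by more than 5 % relative; lone source values on
other dates are used as-is. This favors internal consistency over
unknowable source-system behavior.

## PCOS–metformin exclusion

Metformin is commonly prescribed for polycystic ovarian syndrome, so a
metformin order alone is weak diabetes evidence in that context. The DM
flag is cleared when *all four* hold: DM qualified solely via the
medication pathway; every anti-hyperglycemic order is metformin; a PCOS
diagnosis code exists; and no prediabetes criterion is met. Only the DM
flag is touched — the patient remains in the registry iff another
condition qualifies — and `pcos_excluded_dm` records the action. Reading
the exclusion as flag-level (not whole-patient removal) is a deliberate
design choice: evidence for an unrelated condition is unaffected by why
metformin was prescribed.

## Temporal-window conventions and a documented ambiguity

Guideline phrasings of the blood-pressure separation differ between "at
least 14 days apart" and "> 14 days apart". The engine defaults to the
inclusive reading (gap ≥ 14) and exposes `windows.bp_gap_strict` to flip
to the strict one; both behaviors are tested. Similarly, UACR and UPCR
measurements may mix within one albuminuria pair by default (they are
two markers of the same finding); `albuminuria_mixed_markers: false`
requires same-marker pairs.

Inequality directions are fixed: eGFR < 60 is strict; every other
threshold (UACR ≥ 30 mg/g, UPCR ≥ 150 mg/g, HbA1c ≥ 6.5 %/≥ 5.7 %,
glucose ≥ 200/≥ 126/≥ 140/≥ 100 mg/dL, SBP ≥ 140, DBP ≥ 90 mm Hg) is
inclusive, and the prediabetes bands (5.7–6.4 %, 140–199 mg/dL,
100–125 mg/dL) are closed intervals. A two-point boundary test per
threshold and window pins each direction.

## Geography

Zip codes (ZIP+4 truncated to 5 digits) map through a zip → RUCA
crosswalk; RUCA secondary codes partition into urban
({1.0, 1.1, 2.0, 2.1, 3.0, 4.1, 5.1, 7.1, 8.1, 10.1}) and rural (the
remaining 23 secondary codes). The partition ships as an editable CSV.
Missing, malformed and unmapped zips each get a distinct reason but the
same `unclassified` category, so urban + rural + unclassified always
equals the cohort size. Classification depends only on (zip, crosswalk).
The crosswalk bundled with synthetic cohorts is itself synthetic (zips
90000–90065 cycling through all 33 secondary codes); real deployments
point the config at a published crosswalk file.

## The synthetic cohort generator

The generator emulates the *data classes* the rules consume, not
disease biology. Each patient receives planted patterns plus background
events drawn strictly inside non-qualifying ranges (HbA1c 4.6–5.5 %,
fasting glucose 75–98, random glucose 85–138 mg/dL, BP below 139/88,
eGFR 75–115, benign diagnoses and medications), so ground truth is
defined entirely by which clause was planted — the generator never
consults the engine, keeping label recovery a genuine two-implementation
check. The library covers one qualifying pattern per rule clause
(16), one near-miss per clause that fails exactly one condition — gap
one day short, value at the wrong side of a boundary, same-day pair,
single code where two are required — (15), plus PCOS-exclusion and
pediatric scenarios (3). The first 34 patients of any cohort receive the
library round-robin (values and dates still randomized), so every
clause is exercised at any cohort size ≥ 34 for every seed; remaining
patients draw per-condition Bernoulli mixes, near-misses, or
background-only streams.

Default study conditions: 1000 patients per cohort; condition
plant rates CKD 0.12, HTN 0.35, DM 0.15, prediabetes 0.20 (hypertension
most common and diabetes roughly a third of at-risk membership, the
ordering seen in at-risk CKD populations); near-miss rate 0.15 to stress
boundaries; missing-zip fraction 0.011; an 11-year observation window
(2006-01-01 to 2017-12-31); background events Poisson(2) per patient.
Creatinine values for eGFR patterns are obtained by numerically
inverting the configured CKD-EPI equation at the target eGFR (bisection
to 1e-6), so planted CKD patterns exercise the eGFR module end to end;
about 20 % of creatinine rows are emitted in µmol/L to exercise unit
normalization.

What the generator does **not** emulate: realistic visit cadence or
disease progression, correlation between conditions beyond independent
planting, inter-system documentation differences, coding error or
miscoded settings, and real RUCA geography. Passing the recovery tests
therefore demonstrates that the rules are implemented exactly as
specified — not that the rules themselves are clinically complete, nor
how they behave under real-world data quality.

## Numerical and degenerate-input choices

* Ages are completed years at the event date (birthday convention);
  the pediatric/adult dispatch boundary is exactly the 18th birthday.
* CKD-EPI is continuous at Scr = κ and strictly decreasing in Scr;
  both are asserted to 1e-9 on a covariate grid.
* Pair search returns the earliest qualifying pair (scanning first
  members in date order); verdicts depend only on existence.
* Duplicate identical rows are quarantined with reason `duplicate row`
  at ingest (so per-table row counts reconcile exactly); same-day rows
  with different values are all kept as distinct observations.
* Row-level validation failures (unparseable dates/values, negative
  labs, SBP ≤ DBP, unknown units, events before birth, unknown
  patients) are quarantined to `rejects.csv` with reasons, never
  silently dropped. A missing required column is fatal.
* Empty cohorts produce all-zero reports; a record with no events is a
  valid non-member.

## Reproducibility

All randomness lives in the generator and flows from a single seed; the
engine is deterministic. Outputs are bit-stable: patients are processed
in sorted-id order, attrition JSON has sorted keys and no timestamps
(timing lives in `manifest.json`), and re-running a pipeline with the
same inputs reproduces `registry.csv`, `evidence.csv` and
`attrition.json` byte-for-byte. The run manifest records the resolved
configuration and its SHA-256 hash.

The test suite and the acceptance script use cohorts of 1000 patients
(10 seeds for recovery, 500 boundary-heavy mini-patients for the
brute-force oracle comparison); these sizes give full pattern coverage
with comfortable margins while keeping a complete run in seconds.

## Known limitations

* Condition onset dating, CKD staging (G/A stages), and eGFR-slope or
  rapid-progression flags are out of scope.
* The medication lexicon is a compact ingredient-substring map intended
  for synthetic and demonstration data; production use requires a
  curated formulary (e.g., RxNorm-derived) mapped into the same config
  section.
* No FHIR/OMOP ingestion; inputs are the five documented CSV tables.
* Survival/longitudinal modeling of outcomes is deliberately not
  included; this package produces the cohort, flags and evidence trail
  such analyses start from.
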