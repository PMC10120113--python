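# Methods

`hypnotrend` implements a claims-database drug-utilization analysis of
hypnotic prescribing for insomnia: per-fiscal-year identification of *new*
and *long-term* hypnotic users, and descriptive trend/pattern tabulation of
the mechanism-of-action (MOA) classes they are prescribed. Real data of this
kind (Japanese employment-based insurance claims) are proprietary, so the
package ships a generator that emulates their structure with ground-truth
labels; every empirical statement below is one the test suite computes.

## Study design

The unit of analysis is the **patient-year**. Each fiscal year (April 1 to
March 31, labelled by its starting calendar year) a member's **index date**
is the first outpatient hypnotic claim carrying a bedtime-administration
instruction. Only bedtime outpatient prescriptions are analytic claims:
in the emulated source, administration-timing instructions exist only on
outpatient pharmacy claims, and drugs approved for both anxiety and insomnia
count only when prescribed for bedtime use.

Eligibility gates, applied in order at the index date:

1. ≥ 1 outpatient insomnia diagnosis (ICD-10 `G470`) on or before the index
   date (the source ties the prescription to a diagnosis without stating a
   window; we read this permissively, any time on or before index, and leave
   the window configurable);
2. age ≥ 20 and < 75 years, computed in completed years at month precision
   (claims carry birth year-month only, so the day of month is ignored);
3. continuous enrolment across the whole **baseline window** — the
   `baseline_months` (default 12) calendar months ending the day before the
   index date, with end-of-month clamping. "Continuous" defaults to
   gap-free (`enrollment_max_gap_days = 0`); the gap allowance exists for
   sensitivity analyses because administrative enrolment data sometimes
   contain bridgeable seams.

Exclusions: a narcolepsy/cataplexy code (`G474`) anywhere in the configured
study window (not merely pre-index); any inpatient claim dated the index
date; any hypnotic claim of the member with a missing dispense date; only
PRN-flagged hypnotics on the index date (one scheduled claim rescues the
member — the rule is "PRN *only*"); and hypnotic supplies from ≥ 2 distinct
institutions whose coverage intervals both contain the index date
(doctor-shopping / double-coverage signal).

User types:

* **new** — no hypnotic dispense date anywhere in the baseline window. The
  check uses dispense dates only: a claim issued before the window whose
  supply leaks into it does not disqualify (prescribing, not coverage, is
  the washout concept; a coverage-based variant is a sensitivity switch).
* **long-term** — some single-MOA coverage episode contains the index date
  and started at least `long_term_days` (default 180) days before it,
  i.e. episode start ≤ index − 180, giving ≥ 181 covered-or-bridged days
  through the index inclusive.
* **neither** — prior use without 180-day single-class continuity
  (switchers, intermittent users). These member-years stay in the audit log
  with reason `neither_user_type` but join no cohort; the two definitions
  are provably disjoint (an empty baseline cannot contain a 180-day
  episode), which the suite asserts.

## Coverage episodes

Episodes are built per member × MOA class by chaining claim supply intervals
`[dispense, dispense + days_supplied − 1]`; a claim extends the running
episode when at most `grace_days` uncovered days separate it from the
covered end. All generics of one class pool into a single stream — switching
benzodiazepines never breaks a BZD episode. Overlapping refills extend
coverage by union (no stockpiling). PRN claims count toward coverage: PRN
status matters at the index date only.

The source never defines "continuous prescription", so the grace period is
the package's main free parameter. The default is **30 days** — one missed
refill cycle, matching the dominant 30-day per-prescription caps in the
formulary — with 0 and 7 as conventional presets. Grace is monotone:
increasing it can only merge episodes, never split them (property-tested).

## Formulary

24 generics in five MOA classes (12 BZD, 3 z-drugs, ramelteon, suvorexant,
7 barbiturate/miscellaneous "Others"); BZD and z-drugs carry a
duration-of-action subtype. Lookup is by generic name, case-insensitive,
never by ATC (three entries have none). Per-prescription day caps drive an
advisory QC flag only and never exclude claims; phenobarbital's 30–90 range
is stored as the permissive 90 to avoid false-positive flags. Lemborexant
is deliberately absent (not marketed in the study window); classifying it
raises.

## Tabulation

Trend tables give, per fiscal year and user type, the distribution over
{BZD, Z_DRUG, MRA, ORA, OTHER, multiple}, where *multiple* means ≥ 2
distinct classes on the index day. Pattern tables pool a fiscal-year window
(default 2018–2019) **as patient-years**: a member indexed in both years
contributes twice, because the per-year cohorts are patient-year constructs
(a deduplicated variant would need a tie-break the source does not state).
Nested distributions use the stated denominators: duration types among
everyone prescribed a BZD (alone or in combination), combination labels
among multiple-MOA members.

Comorbidity flags come from baseline-window ICD-10 category prefixes:
substance use F10–F19, schizophrenia spectrum F20–F29, bipolar F30–F31,
depressive F32–F33, anxiety F40–F42, neurocognitive restricted to
Alzheimer's disease (F00, G30 only — F03 falls to the residual), and a
residual "others" for any other F-chapter code. Flags are non-exclusive.

Proportions are reported as count/denominator with a two-sided 95% CI,
default **Wald** (`statsmodels` `proportion_confint`, clipped to [0, 100]),
Wilson available. At cohort-scale denominators the two are numerically
indistinguishable; at the published table's sizes Wald reproduces the
printed sex-row CI bounds exactly. One borderline cell (depressive
disorders among new users, upper bound printing 15.7) rounds to 15.6 under
Wald but 15.7 under Wilson — the source's SAS method is unstated.
Percent rounding is one decimal, half away from zero, at display only; all
partition identities are asserted on unrounded counts.

## Synthetic generator

Archetype-first: each member's intended label is drawn, then claims are
synthesized to satisfy it — incident starters (empty baseline), persistent
users (same-MOA chains starting 200–320 days before the target fiscal year
with gaps ≤ the chaining slack), switchers (~2–5 months of one class then a
second class through the index, neither reaching 180 days), intermittent
users (an isolated baseline claim ≥ 200 days before an isolated index
claim), and ineligible decoys violating exactly one rule each (seven kinds,
cycled). Default mixes state the emulated world: archetypes
40/25/15/15/5 (%), demographic and MOA-category weights mirroring the
published 2018–2019 cohort (the multi-MOA share is encoded directly in the
combination labels' weights rather than a separate rate dial), day supplies
drawn from {14, 28, 30} truncated at each drug's cap, and contamination
rates (PRN-only, second prescriber, narcolepsy) of 0 in acceptance
scenarios.

What a green recovery test establishes: with the pipeline grace matched to
the generator slack, intended labels are recovered exactly (0 errors at
n = 5,000 over 20 seeds). What it does not: realism of Japanese insurance
dynamics, dose/strength behaviour, or calibration beyond the configured
mixes. Two structural caveats: ground truth labels each member's one
*target* fiscal year, while a persister's pre-index chain necessarily also
creates an (unlabelled, audited) index in the preceding year; and each
member is assigned a single institution, so the multi-prescriber exclusion
occurs only where planted.

## Numerical and determinism choices

Dates are integer day numbers internally; interval merging is a single
vectorized sort/cummax pass, identical machinery for enrolment and
episodes. Index-day institution ties are broken by earliest record order.
Pipelines are rerun-deterministic (bit-identical frames and output bytes);
the run manifest carries a wall-clock timestamp, so determinism is asserted
on the data outputs and the manifest's digest map. Randomness exists only
in the generator, seeded through a single NumPy `default_rng`.

## Known limitations

* The long-term rule is supply-based chaining; whether the source chained
  on dispense dates alone is unstated, and a dispense-date-only variant is
  not implemented.
* No stockpiling semantics, dose information, inpatient prescribing, or
  cross-class (any-hypnotic) episodes.
* The published figure-level results require the proprietary source
  database; synthetic runs reproduce structure, not its real-data values.
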