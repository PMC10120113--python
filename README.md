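# hypnotrend

A tested pipeline for claims-database drug-utilization analysis of hypnotic
prescribing in insomnia: drug-era (coverage-episode) construction, new-user
versus long-term-user cohort identification per fiscal year, and descriptive
trend/pattern tables with 95% confidence intervals.

It is written for pharmacoepidemiologists who study prescribing of insomnia
medications — benzodiazepines (BZD), non-benzodiazepine GABA_A agonists
(z-drugs), the melatonin receptor agonist ramelteon (MRA), the orexin
receptor antagonist suvorexant (ORA), and older "other" sedatives — in
longitudinal administrative claims. Because such databases are proprietary,
the package also ships a synthetic claims generator with ground-truth
labels, so the whole analysis is reproducible and testable offline.

## The core definitions

For each fiscal year (April 1 – March 31, labelled by its starting year) a
member's **index date** is the first outpatient, bedtime-instruction
hypnotic claim. After eligibility gates (insomnia diagnosis G470 on or
before index, age 20–74, ≥ 12 months continuous enrolment) and exclusions
(narcolepsy G474, inpatient at index, missing dispense dates, PRN-only at
index, overlapping supplies from ≥ 2 prescribers), each patient-year is:

* **new**: no hypnotic dispensed in the 12-month baseline window
  `[index − 12 months, index − 1 day]`;
* **long-term**: a same-MOA coverage episode contains the index date and
  started ≥ 180 days before it. Episodes chain supply intervals
  `[dispense, dispense + days_supplied − 1]` per MOA class, bridging
  uncovered gaps ≤ `grace_days` (default 30, one refill cycle);
* **neither**: prior use without 180-day single-class continuity (audited,
  not analyzed).

Every category cell is reported as *n* (%) with a two-sided 95% CI,
Wald by default: `p̂ ± 1.96·√(p̂(1−p̂)/n)`, Wilson optional.

## Worked example

```python
from hypnotrend import ScenarioConfig, generate, build_cohort, trend_by_year

scenario = ScenarioConfig(n_members=1000, seed=7)   # emulated claims world
dataset, truth = generate(scenario)
cohort, audit = build_cohort(dataset, scenario.recommended_config())
print(f"decisions: {len(audit)}, included patient-years: {len(cohort)}")
print(trend_by_year(cohort, "new", fiscal_years=[2019]).round(1).to_string(index=False))
```

prints

```
decisions: 1288, included patient-years: 927
 fiscal_year category  count  denominator  pct  ci_low  ci_high
        2019      BZD     56          189 29.6    23.1     36.1
        2019   Z_DRUG     68          189 36.0    29.1     42.8
        2019      MRA     13          189  6.9     3.3     10.5
        2019      ORA     45          189 23.8    17.7     29.9
        2019    OTHER      1          189  0.5     0.0      1.6
        2019 multiple      6          189  3.2     0.7      5.7
```

Of 1,288 member-years with an index date, 927 entered a cohort; among the
189 FY2019 new users, z-drugs were the most common first hypnotic (36.0%,
95% CI 29.1–42.8), with ~3% starting on two or more MOA classes at once —
the generated world mirrors the prescribing mix its scenario states, and the
estimates recover those planted weights within binomial noise. The `truth`
table carries each member's intended label for exact-recovery checks
(`hypnotrend.recovery_report`).

The same workflow is available from a shell:

```sh
hypnotrend simulate --out demo/data --seed 7
hypnotrend run --data demo/data --out demo/results
cat demo/results/report.txt      # patient-flow block per fiscal year
```

`demo/results/` then contains the episode, cohort and audit tables, tidy
trend/pattern CSVs (counts, denominators, percentages, CI bounds), and a
`manifest.json` recording the configuration, digests and row counts of the
run. See `docs/data_dictionary.md` for the file formats and
`docs/methods.md` for the analytic choices and their rationale.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a 2,000-member scenario from scratch, runs the full pipeline
(validation → episodes → cohort → trend and pattern tables → ground-truth
recovery), prints a one-line summary, and writes the results JSON.
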