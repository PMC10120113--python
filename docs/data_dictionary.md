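# Claims-table data dictionary

All tables are delimited UTF-8 text with a header row (comma-separated for
`.csv`, tab-separated for `.tsv`). Dates are ISO 8601 (`YYYY-MM-DD`) at day
precision; every interval is closed (`[start, end]`, both endpoints covered).
Boolean flags are the literals `true` / `false`.

## members.csv

| column | type | notes |
|---|---|---|
| `member_id` | text | unique within the dataset |
| `birth_year_month` | `YYYY-MM` | month precision, as carried by claims databases |
| `sex` | `male` \| `female` | |

## enrollment.csv

| column | type | notes |
|---|---|---|
| `member_id` | text | must exist in members |
| `start_date` | date | `start_date <= end_date` |
| `end_date` | date | interval is closed |

Multiple rows per member are allowed; the pipeline merges them (the
`enrollment_max_gap_days` setting controls how large an uncovered gap still
counts as continuous; the default 0 bridges only abutting intervals).

## diagnoses.csv

| column | type | notes |
|---|---|---|
| `member_id` | text | must exist in members |
| `claim_date` | date | |
| `icd10_code` | text | one letter + 2–3 digits, e.g. `G470`, `F32`, `F329` |
| `setting` | `outpatient` \| `inpatient` | |

## prescriptions.csv

| column | type | notes |
|---|---|---|
| `member_id` | text | must exist in members |
| `dispense_date` | date or empty | empty = missing date (triggers the member-level exclusion) |
| `generic_name` | text | must resolve in the drug dictionary (case-insensitive) |
| `days_supplied` | integer ≥ 1 | supply covers `[dispense_date, dispense_date + days_supplied − 1]` |
| `bedtime_flag` | boolean | only bedtime-instruction prescriptions enter the analysis |
| `prn_flag` | boolean | *pro re nata* (as-needed) instruction |
| `institution_id` | text | must exist in institutions |
| `setting` | `outpatient` \| `inpatient` | only outpatient claims enter the analysis |

## institutions.csv

| column | type | notes |
|---|---|---|
| `institution_id` | text | unique |
| `primary_department` | `psychiatry` \| `other` | |
| `n_beds` | integer ≥ 0 | clinic = 0–19 beds, hospital = ≥ 20 beds |

## Drug dictionary (`hypnotic_formulary.csv`, packaged)

| column | type | notes |
|---|---|---|
| `generic_name` | text | lookup key, case-insensitive |
| `moa_class` | `BZD` \| `Z_DRUG` \| `MRA` \| `ORA` \| `OTHER` | |
| `duration_type` | `long` \| `intermediate` \| `short` \| `ultrashort` or empty | set exactly for BZD/Z_DRUG |
| `atc_code` | text or empty | informational only; matching is by name |
| `max_days_per_rx` | integer or empty | empty = unrestricted; advisory QC only |
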