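"""Per-fiscal-year cohorts of new and long-term hypnotic users.

The unit of analysis is the patient-year: within each fiscal year (April 1 to
March 31, labelled by its starting calendar year) a member's index date is the
first bedtime outpatient hypnotic claim.  Members then pass, in order:

1. eligibility gates -- an insomnia diagnosis (ICD-10 G470, outpatient) on or
   before the index date; age >= 20 and < 75 at index; continuous enrolment
   over the full baseline window (the 12 calendar months ending the day
   before the index date);
2. exclusions -- narcolepsy/cataplexy (G474) anywhere in the study window;
   any inpatient claim on the index date; any hypnotic claim with a missing
   dispense date; only PRN ("as needed") hypnotics on the index date;
   overlapping hypnotic coverage from >= 2 institutions at the index date;
3. user-type classification -- *new* if the baseline window contains no
   hypnotic dispense date at all; *long-term* if a single-MOA coverage
   episode contains the index date and started >= 180 days before it;
   otherwise *neither* (retained in the audit log, absent from the cohort).

New and long-term are mutually exclusive by construction: a new user's
baseline is empty while a long-term user needs ~6 months of pre-index
coverage.  Every member-year with an index date receives exactly one
eligibility decision, so cohort size plus exclusion counts reconciles with
the number of indexed member-years (flow-diagram conservation).
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .claims_model import ClaimsDataset, from_day, merge_enrollment, series_to_day, to_day
from .drug_dictionary import DrugEntry
from .episode_engine import DEFAULT_GRACE_DAYS, build_episodes, classify_prescriptions
from . import tabulation

__all__ = [
    "AnalysisConfig",
    "EligibilityDecision",
    "REASON_CODES",
    "fiscal_year_of",
    "fiscal_year_start",
    "fiscal_year_end",
    "shift_months",
    "age_at",
    "index_date_in_period",
    "check_eligibility",
    "apply_exclusions",
    "classify_user",
    "build_cohort",
]

#: Canonical audit order of eligibility/exclusion reason codes.
REASON_CODES = (
    "no_insomnia_dx",
    "no_hypnotic",
    "age_out_of_range",
    "insufficient_enrollment",
    "narcolepsy",
    "inpatient_at_index",
    "missing_rx_date",
    "prn_only_at_index",
    "multi_prescriber_overlap_at_index",
    "neither_user_type",
)


def fiscal_year_of(date: dt.date) -> int:
    """Fiscal-year label (the calendar year of the April 1 starting the period)."""
    return date.year if date.month >= 4 else date.year - 1


def fiscal_year_start(fy: int) -> dt.date:
    return dt.date(fy, 4, 1)


def fiscal_year_end(fy: int) -> dt.date:
    return dt.date(fy + 1, 3, 31)


def shift_months(date: dt.date, months: int) -> dt.date:
    """Calendar-month shift with end-of-month clamping."""
    m = date.month - 1 + months
    y = date.year + m // 12
    m = m % 12 + 1
    return dt.date(y, m, min(date.day, calendar.monthrange(y, m)[1]))


@dataclass
class AnalysisConfig:
    """Every analytic threshold of the pipeline; no constant lives elsewhere.

    Defaults state the study design: data window April 2009 - March 2020,
    analysis periods FY2010-FY2019, a 12-month baseline, the 180-day
    long-term threshold, ages 20-74, a 30-day episode grace period, strict
    (gap-free) enrolment continuity and Wald confidence intervals.
    """

    study_start: dt.date = dt.date(2009, 4, 1)
    study_end: dt.date = dt.date(2020, 3, 31)
    first_fiscal_year: int | None = None
    last_fiscal_year: int | None = None
    baseline_months: int = 12
    long_term_days: int = 180
    age_min_inclusive: int = 20
    age_max_exclusive: int = 75
    grace_days: int = DEFAULT_GRACE_DAYS
    enrollment_max_gap_days: int = 0
    ci_method: str = "wald"
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.study_start, str):
            self.study_start = dt.date.fromisoformat(self.study_start)
        if isinstance(self.study_end, str):
            self.study_end = dt.date.fromisoformat(self.study_end)
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.baseline_months < 1 or self.long_term_days < 1:
            raise ValueError("baseline_months and long_term_days must be >= 1")
        if self.grace_days < 0 or self.enrollment_max_gap_days < 0:
            raise ValueError("grace/gap day settings must be >= 0")
        if self.ci_method not in ("wald", "wilson"):
            raise ValueError("ci_method must be 'wald' or 'wilson'")

    def fiscal_years(self) -> list[int]:
        """Analysis periods; defaults leave the first year as pure baseline."""
        first = self.first_fiscal_year
        if first is None:
            first = fiscal_year_of(shift_months(self.study_start, self.baseline_months))
        last = self.last_fiscal_year
        if last is None:
            last = fiscal_year_of(self.study_end)
            if fiscal_year_end(last) > self.study_end:
                last -= 1
        return list(range(first, last + 1))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class EligibilityDecision:
    member_id: str
    fiscal_year: int
    status: str  # included_new | included_long_term | excluded
    reason_codes: list[str] = field(default_factory=list)


def age_at(birth_year_month: str, index_date: dt.date) -> int:
    """Completed years from birth year-month to index year-month.

    Claims data carry birth at month precision; the day of month is ignored
    (floor), so a member turns 20 analytically on the first of their birthday
    month.
    """
    by, bm = int(birth_year_month[:4]), int(birth_year_month[5:7])
    diff = (index_date.year - by) * 12 + (index_date.month - bm)
    if diff < 0:
        raise ValueError(f"birth {birth_year_month} after index {index_date}")
    return diff // 12


def _ordered(reasons: set[str]) -> list[str]:
    return [r for r in REASON_CODES if r in reasons]


class _Workspace:
    """Pre-grouped views of one dataset under one config (shared by the ops)."""

    def __init__(self, dataset: ClaimsDataset, config: AnalysisConfig,
                 dictionary: Sequence[DrugEntry] | None = None):
        self.config = config
        self.dataset = dataset
        rx = classify_prescriptions(dataset.prescriptions, dictionary)
        self.rx_all = rx
        has_date = rx["dispense_date"].notna()
        self.missing_rx_members = set(rx.loc[~has_date, "member_id"])

        arx = rx[has_date & rx["bedtime_flag"] & (rx["setting"] == "outpatient")].reset_index(drop=True)
        self.arx = arx
        self._arx_day = series_to_day(arx["dispense_date"]) if len(arx) else np.empty(0, dtype="int64")
        self._arx_end = self._arx_day + (arx["days_supplied"].to_numpy() if len(arx) else 0) - 1
        self._arx_moa = arx["moa_class"].to_numpy()
        self._arx_generic = arx["generic_name"].astype(str).str.strip().str.lower().to_numpy()
        self._arx_prn = arx["prn_flag"].to_numpy()
        self._arx_inst = arx["institution_id"].to_numpy()
        self._arx_groups = {m: idx for m, idx in arx.groupby("member_id", sort=False).indices.items()}

        # index dates per member-year
        if len(arx):
            fy = np.where(
                arx["dispense_date"].dt.month >= 4,
                arx["dispense_date"].dt.year,
                arx["dispense_date"].dt.year - 1,
            )
            idx_frame = pd.DataFrame({"member_id": arx["member_id"], "fy": fy, "day": self._arx_day})
            self.index_map = idx_frame.groupby(["member_id", "fy"], sort=False)["day"].min().to_dict()
        else:
            self.index_map = {}

        dx = dataset.diagnoses
        g470 = dx[(dx["icd10_code"] == "G470") & (dx["setting"] == "outpatient")]
        self._g470_days = {
            m: np.sort(series_to_day(grp["claim_date"])) for m, grp in g470.groupby("member_id", sort=False)
        }
        in_window = (dx["claim_date"] >= pd.Timestamp(config.study_start)) & (
            dx["claim_date"] <= pd.Timestamp(config.study_end)
        )
        self.narcolepsy_members = set(dx.loc[(dx["icd10_code"] == "G474") & in_window, "member_id"])

        inpat_days: dict[str, set[int]] = {}
        inpat_dx = dx[dx["setting"] == "inpatient"]
        for m, d in zip(inpat_dx["member_id"], series_to_day(inpat_dx["claim_date"])):
            inpat_days.setdefault(m, set()).add(int(d))
        inpat_rx = rx[(rx["setting"] == "inpatient") & has_date]
        for m, d in zip(inpat_rx["member_id"], series_to_day(inpat_rx["dispense_date"])):
            inpat_days.setdefault(m, set()).add(int(d))
        self.inpatient_days = inpat_days

        enr = merge_enrollment(dataset.enrollment, config.enrollment_max_gap_days)
        self._enr = {
            m: (series_to_day(grp["start_date"]), series_to_day(grp["end_date"]))
            for m, grp in enr.groupby("member_id", sort=False)
        }

        self.episodes = build_episodes(arx, dictionary, config.grace_days)
        self._episodes_by_member = {
            m: (grp["moa_class"].to_numpy(), grp["start_day"].to_numpy(), grp["end_day"].to_numpy())
            for m, grp in self.episodes.groupby("member_id", sort=False)
        }

        self._dx_days = {}
        self._dx_cat3 = {}
        cat3 = dx["icd10_code"].astype(str).str.upper().str.slice(0, 3).to_numpy()
        days = series_to_day(dx["claim_date"]) if len(dx) else np.empty(0, dtype="int64")
        for m, idx in dx.groupby("member_id", sort=False).indices.items():
            self._dx_days[m] = days[idx]
            self._dx_cat3[m] = cat3[idx]

        self._members = dataset.members.set_index("member_id")
        self._institutions = dataset.institutions.set_index("institution_id")
        self._duration_by_generic = None
        if len(arx):
            self._arx_duration = arx["duration_type"].to_numpy()
        else:
            self._arx_duration = np.empty(0, dtype=object)

    # -- rule blocks -------------------------------------------------------

    def gate_reasons(self, member_id: str, index_day: int) -> set[str]:
        reasons: set[str] = set()
        g470 = self._g470_days.get(member_id)
        if g470 is None or not (g470[0] <= index_day):
            reasons.add("no_insomnia_dx")
        birth = self._members.at[member_id, "birth_year_month"]
        age = age_at(birth, from_day(index_day))
        if not (self.config.age_min_inclusive <= age < self.config.age_max_exclusive):
            reasons.add("age_out_of_range")
        baseline_start = to_day(shift_months(from_day(index_day), -self.config.baseline_months))
        starts_ends = self._enr.get(member_id)
        covered = False
        if starts_ends is not None:
            s, e = starts_ends
            covered = bool(np.any((s <= baseline_start) & (e >= index_day - 1)))
        if not covered:
            reasons.add("insufficient_enrollment")
        return reasons

    def exclusion_reasons(self, member_id: str, index_day: int) -> set[str]:
        reasons: set[str] = set()
        if member_id in self.narcolepsy_members:
            reasons.add("narcolepsy")
        if index_day in self.inpatient_days.get(member_id, ()):
            reasons.add("inpatient_at_index")
        if member_id in self.missing_rx_members:
            reasons.add("missing_rx_date")
        idx = self._arx_groups.get(member_id, np.empty(0, dtype="int64"))
        on_index = idx[self._arx_day[idx] == index_day]
        if len(on_index) and bool(self._arx_prn[on_index].all()):
            reasons.add("prn_only_at_index")
        covering = idx[(self._arx_day[idx] <= index_day) & (self._arx_end[idx] >= index_day)]
        if len(set(self._arx_inst[covering])) >= 2:
            reasons.add("multi_prescriber_overlap_at_index")
        return reasons

    def user_type(self, member_id: str, index_day: int) -> str:
        cfg = self.config
        baseline_start = to_day(shift_months(from_day(index_day), -cfg.baseline_months))
        idx = self._arx_groups.get(member_id, np.empty(0, dtype="int64"))
        days = self._arx_day[idx]
        if not np.any((days >= baseline_start) & (days <= index_day - 1)):
            return "new"
        ep = self._episodes_by_member.get(member_id)
        if ep is not None:
            _, s, e = ep
            if bool(np.any((s <= index_day - cfg.long_term_days) & (s <= index_day) & (e >= index_day))):
                return "long_term"
        return "neither"

    # -- covariates --------------------------------------------------------

    def cohort_row(self, member_id: str, fy: int, index_day: int, user_type: str) -> dict:
        cfg = self.config
        idx = self._arx_groups[member_id]
        on_index = idx[self._arx_day[idx] == index_day]
        classes = set(self._arx_moa[on_index])
        category = tabulation.moa_category_from_classes(classes)
        n_hyp = len(set(self._arx_generic[on_index]))
        bzd_duration = ""
        if "BZD" in classes:
            types = {self._arx_duration[i] for i in on_index if self._arx_moa[i] == "BZD"}
            bzd_duration = types.pop() if len(types) == 1 else "two_or_more_types"
        # specialty/setting from the index-day claim earliest in record order
        inst_id = self._arx_inst[on_index.min()]
        dept = self._institutions.at[inst_id, "primary_department"]
        beds = int(self._institutions.at[inst_id, "n_beds"])
        if dept == "psychiatry":
            specialty = "psychiatry"
        elif beds <= 19:
            specialty = "GP"
        else:
            specialty = "others"
        setting = "clinic" if beds <= 19 else "hospital"

        baseline_start = to_day(shift_months(from_day(index_day), -cfg.baseline_months))
        dxd = self._dx_days.get(member_id)
        if dxd is None:
            flags = {name: False for name in tabulation.COMORBIDITY_NAMES}
        else:
            mask = (dxd >= baseline_start) & (dxd <= index_day - 1)
            flags = tabulation.flags_from_codes(self._dx_cat3[member_id][mask])
        birth = self._members.at[member_id, "birth_year_month"]
        age = age_at(birth, from_day(index_day))
        row = {
            "member_id": member_id,
            "fiscal_year": fy,
            "user_type": user_type,
            "index_date": pd.Timestamp(from_day(index_day)),
            "age_at_index": age,
            "age_group": tabulation.age_group_of(age),
            "sex": self._members.at[member_id, "sex"],
            "moa_kind": category.kind,
            "moa_label": category.combo_label,
            "bzd_duration": bzd_duration,
            "specialty": specialty,
            "setting": setting,
            "n_hypnotics": n_hyp,
        }
        for name in tabulation.COMORBIDITY_NAMES:
            row[f"cm_{name}"] = flags[name]
        return row

    def decide(self, member_id: str, fy: int) -> tuple[EligibilityDecision, dict | None]:
        index_day = self.index_map[(member_id, fy)]
        reasons = self.gate_reasons(member_id, index_day)
        if not reasons:
            reasons = self.exclusion_reasons(member_id, index_day)
        if reasons:
            return EligibilityDecision(member_id, fy, "excluded", _ordered(reasons)), None
        utype = self.user_type(member_id, index_day)
        if utype == "neither":
            return EligibilityDecision(member_id, fy, "excluded", ["neither_user_type"]), None
        status = "included_new" if utype == "new" else "included_long_term"
        return (
            EligibilityDecision(member_id, fy, status, []),
            self.cohort_row(member_id, fy, index_day, utype),
        )


# ---------------------------------------------------------------------------
# Public operations (thin wrappers over the workspace)
# ---------------------------------------------------------------------------

def index_date_in_period(
    member_id: str, fiscal_year: int, dataset: ClaimsDataset,
    dictionary: Sequence[DrugEntry] | None = None,
) -> dt.date | None:
    """Earliest bedtime outpatient hypnotic dispense date within the fiscal year."""
    rx = dataset.prescriptions
    sel = rx[
        (rx["member_id"] == member_id)
        & rx["bedtime_flag"]
        & (rx["setting"] == "outpatient")
        & rx["dispense_date"].notna()
        & (rx["dispense_date"] >= pd.Timestamp(fiscal_year_start(fiscal_year)))
        & (rx["dispense_date"] <= pd.Timestamp(fiscal_year_end(fiscal_year)))
    ]
    if sel.empty:
        return None
    return sel["dispense_date"].min().date()


def check_eligibility(
    member_id: str, fiscal_year: int, dataset: ClaimsDataset, config: AnalysisConfig,
    dictionary: Sequence[DrugEntry] | None = None,
) -> EligibilityDecision:
    """Pre-exclusion gates only (index exists, insomnia dx, age, enrolment)."""
    ws = _Workspace(dataset, config, dictionary)
    key = (member_id, fiscal_year)
    if key not in ws.index_map:
        return EligibilityDecision(member_id, fiscal_year, "excluded", ["no_hypnotic"])
    reasons = ws.gate_reasons(member_id, ws.index_map[key])
    if reasons:
        return EligibilityDecision(member_id, fiscal_year, "excluded", _ordered(reasons))
    return EligibilityDecision(member_id, fiscal_year, "included_new", [])


def apply_exclusions(
    member_id: str, index_date: dt.date, dataset: ClaimsDataset, config: AnalysisConfig,
    dictionary: Sequence[DrugEntry] | None = None,
) -> list[str]:
    """Exclusion reason codes at a given index date (gates assumed passed)."""
    ws = _Workspace(dataset, config, dictionary)
    return _ordered(ws.exclusion_reasons(member_id, to_day(index_date)))


def classify_user(
    member_id: str, index_date: dt.date, dataset: ClaimsDataset, config: AnalysisConfig,
    dictionary: Sequence[DrugEntry] | None = None,
) -> str:
    """'new' / 'long_term' / 'neither' at a given index date."""
    ws = _Workspace(dataset, config, dictionary)
    return ws.user_type(member_id, to_day(index_date))


def build_cohort(
    dataset: ClaimsDataset,
    config: AnalysisConfig | None = None,
    dictionary: Sequence[DrugEntry] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one pass per fiscal year over every member with an index date.

    Returns ``(cohort, audit)``:

    * ``cohort`` -- one row per included patient-year with all covariates
      resolved at the index date;
    * ``audit`` -- one :class:`EligibilityDecision` row per member-year with
      an index date (``reason_codes`` pipe-joined; empty for included rows).

    The run is deterministic: identical inputs give bit-identical frames.
    """
    config = config or AnalysisConfig()
    ws = _Workspace(dataset, config, dictionary)
    years = set(config.fiscal_years())
    keys = sorted((fy, m) for (m, fy) in ws.index_map if fy in years)
    audit_rows, cohort_rows = [], []
    for fy, member in keys:
        decision, row = ws.decide(member, fy)
        audit_rows.append(
            (decision.member_id, decision.fiscal_year, decision.status, "|".join(decision.reason_codes))
        )
        if row is not None:
            cohort_rows.append(row)
    audit = pd.DataFrame(audit_rows, columns=["member_id", "fiscal_year", "status", "reason_codes"])
    cohort_cols = [
        "member_id", "fiscal_year", "user_type", "index_date", "age_at_index", "age_group",
        "sex", "moa_kind", "moa_label", "bzd_duration", "specialty", "setting", "n_hypnotics",
    ] + [f"cm_{n}" for n in tabulation.COMORBIDITY_NAMES]
    cohort = pd.DataFrame(cohort_rows, columns=cohort_cols)
    return cohort, audit
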