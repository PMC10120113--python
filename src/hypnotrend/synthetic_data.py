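"""Archetype-first synthetic claims generator with ground-truth labels.

Real claims data for this kind of drug-utilization study are proprietary, so
every pipeline stage is exercised on generated datasets that mimic the
structure the analysis assumes: members aged 20-74 with enrolment spans,
outpatient insomnia (G470) diagnoses accompanying every hypnotic claim,
bedtime hypnotic prescriptions drawn from the packaged formulary (respecting
per-drug day caps), psychiatric comorbidity codes in baseline windows, and an
institution table carrying specialty and bed counts.

Generation is archetype-first: each member's intended label is drawn first
and claims are then synthesized to satisfy it, which makes the generator a
usable oracle for the cohort classifier.  Archetypes:

* ``incident_starter`` -- empty 12-month baseline, then an index claim
  (intended *new* user);
* ``persistent_user`` -- a same-MOA refill chain starting >= 200 days before
  the target fiscal year with uncovered gaps <= the chaining slack, running
  through the index date (intended *long-term* user);
* ``switcher`` -- one class for ~2-5 months, then a different class through
  the index, so no single class reaches 180 days (intended *neither*);
* ``intermittent_user`` -- an isolated baseline claim >= 200 days before an
  isolated index claim (intended *neither*);
* ``ineligible_decoy`` -- violates exactly one eligibility/exclusion rule
  (seven kinds, cycled deterministically).

Ground truth is emitted for each member's constructed target fiscal year.
Pre-index history of persisters/switchers necessarily also creates an index
in the preceding fiscal year; those spill-over member-years are left
unlabelled and recovery joins on ground-truth keys.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .claims_model import ClaimsDataset, from_day, to_day
from .cohort_builder import AnalysisConfig, fiscal_year_end, fiscal_year_start
from .drug_dictionary import builtin_dictionary
from .tabulation import AGE_GROUPS, COMORBIDITY_NAMES

__all__ = [
    "ScenarioConfig",
    "DECOY_KINDS",
    "generate",
    "recovery_report",
    "RecoveryReport",
]

ARCHETYPES = (
    "incident_starter",
    "persistent_user",
    "switcher",
    "intermittent_user",
    "ineligible_decoy",
)

DECOY_KINDS = (
    "no_insomnia_dx",
    "age_out_of_range",
    "insufficient_enrollment",
    "narcolepsy",
    "inpatient_at_index",
    "prn_only_at_index",
    "multi_prescriber_overlap_at_index",
)

#: ICD-10 category codes drawn per comorbidity category ("others" codes are
#: F-chapter codes outside every named range).
_COMORBIDITY_CODES = {
    "substance_use": ("F10", "F12", "F17", "F19"),
    "schizophrenia_spectrum": ("F20", "F23", "F25", "F29"),
    "bipolar": ("F30", "F31"),
    "depressive": ("F32", "F33"),
    "anxiety": ("F40", "F41", "F42"),
    "neurocognitive": ("F00", "G30"),
    "others": ("F43", "F45", "F48", "F50", "F51", "F60", "F99"),
}

_AGE_BOUNDS = {"20-34": (20, 34), "35-49": (35, 49), "50-64": (50, 64), "65-74": (65, 74)}

# Default MOA-category weights mirror the reported 2018-2019 pattern
# distributions (combination labels carry the multi-MOA share directly).
_DEFAULT_MIX_NEW = {
    "BZD": 0.321, "Z_DRUG": 0.402, "MRA": 0.061, "ORA": 0.187, "OTHER": 0.001,
    "BZD+Z_DRUG": 0.013, "Z_DRUG+ORA": 0.005, "BZD+ORA": 0.004, "BZD+MRA": 0.006,
}
_DEFAULT_MIX_LONGTERM = {
    "BZD": 0.508, "Z_DRUG": 0.256, "MRA": 0.014, "ORA": 0.038, "OTHER": 0.002,
    "BZD+Z_DRUG": 0.111, "BZD+ORA": 0.026, "Z_DRUG+ORA": 0.016, "BZD+MRA": 0.029,
}
_DEFAULT_COMORBIDITY_NEW = {
    "substance_use": 0.010, "schizophrenia_spectrum": 0.036, "bipolar": 0.024,
    "depressive": 0.153, "anxiety": 0.107, "neurocognitive": 0.001, "others": 0.153,
}
_DEFAULT_COMORBIDITY_LONGTERM = {
    "substance_use": 0.029, "schizophrenia_spectrum": 0.271, "bipolar": 0.177,
    "depressive": 0.592, "anxiety": 0.239, "neurocognitive": 0.003, "others": 0.378,
}


def _check_probs(name: str, weights: dict[str, float]) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} weights must sum to 1 (got {total})")
    if any(w < 0 for w in weights.values()):
        raise ValueError(f"{name} weights must be non-negative")


@dataclass
class ScenarioConfig:
    """A stated synthetic world: sizes, mixes and contamination toggles.

    Default demographic and MOA mixes follow the reported 2018-2019 cohort
    characteristics; contamination rates default to 0 (clean acceptance
    scenarios) and are switched on only for robustness scenarios.
    """

    n_members: int = 1000
    fiscal_years: list[int] = field(default_factory=lambda: [2018, 2019])
    age_distribution: dict[str, float] = field(
        default_factory=lambda: {"20-34": 0.264, "35-49": 0.358, "50-64": 0.321, "65-74": 0.057}
    )
    sex_split_male: float = 0.541
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: {
            "incident_starter": 0.40, "persistent_user": 0.25, "switcher": 0.15,
            "intermittent_user": 0.15, "ineligible_decoy": 0.05,
        }
    )
    moa_mix_new: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX_NEW))
    moa_mix_longterm: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX_LONGTERM))
    comorbidity_prevalence_new: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_NEW)
    )
    comorbidity_prevalence_longterm: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_LONGTERM)
    )
    specialty_mix: dict[str, float] = field(
        default_factory=lambda: {"psychiatry": 0.30, "GP": 0.60, "others": 0.10}
    )
    prn_rate: float = 0.0
    multi_prescriber_rate: float = 0.0
    narcolepsy_rate: float = 0.0
    days_supplied_choices: list[int] = field(default_factory=lambda: [14, 28, 30])
    chaining_slack_days: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not self.fiscal_years:
            raise ValueError("at least one fiscal year is required")
        _check_probs("age_distribution", self.age_distribution)
        _check_probs("archetype_mix", self.archetype_mix)
        _check_probs("moa_mix_new", self.moa_mix_new)
        _check_probs("moa_mix_longterm", self.moa_mix_longterm)
        _check_probs("specialty_mix", self.specialty_mix)
        if not 0 <= self.sex_split_male <= 1:
            raise ValueError("sex_split_male must be in [0, 1]")
        for rate in (self.prn_rate, self.multi_prescriber_rate, self.narcolepsy_rate):
            if not 0 <= rate <= 1:
                raise ValueError("contamination rates must be in [0, 1]")
        if self.chaining_slack_days < 0:
            raise ValueError("chaining_slack_days must be >= 0")
        unknown = set(self.archetype_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def recommended_config(self) -> AnalysisConfig:
        """An AnalysisConfig matched to this world (grace = chaining slack)."""
        fy_min, fy_max = min(self.fiscal_years), max(self.fiscal_years)
        return AnalysisConfig(
            study_start=fiscal_year_start(fy_min - 2),
            study_end=fiscal_year_end(fy_max),
            first_fiscal_year=fy_min,
            last_fiscal_year=fy_max,
            grace_days=self.chaining_slack_days,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _class_pools():
    by_class: dict[str, list] = {}
    for e in builtin_dictionary():
        by_class.setdefault(e.moa_class, []).append(e)
    chain = {
        c: [e for e in es if e.max_days_per_rx is None or e.max_days_per_rx >= 28]
        for c, es in by_class.items()
    }
    return by_class, chain


class _Emitter:
    """Accumulates table rows for one generated dataset."""

    def __init__(self):
        self.members: list[tuple] = []
        self.enrollment: list[tuple] = []
        self.diagnoses: list[tuple] = []
        self.prescriptions: list[tuple] = []
        self.institutions: list[tuple] = []

    def rx(self, member, day, entry, days_supplied, inst, *, prn=False, bedtime=True,
           setting="outpatient", with_dx=True):
        self.prescriptions.append(
            (member, day, entry.generic_name, int(days_supplied), bedtime, prn, inst, setting)
        )
        if with_dx:
            self.diagnoses.append((member, day, "G470", "outpatient"))

    def dx(self, member, day, code, setting="outpatient"):
        self.diagnoses.append((member, day, code, setting))


def _supply(rng, entry, choices) -> int:
    s = int(rng.choice(choices))
    if entry.max_days_per_rx is not None:
        s = min(s, entry.max_days_per_rx)
    return s


def _chain_dates(rng, start_day: int, until_day: int, slack: int) -> list[tuple[int, int]]:
    """(claim day, supply) pairs covering [start_day .. >= until_day] with
    uncovered gaps <= slack."""
    out = []
    t = start_day
    covered = start_day - 1
    while covered < until_day:
        s = int(rng.choice((28, 30)))
        out.append((t, s))
        covered = t + s - 1
        gap = int(rng.integers(0, slack + 1)) if slack else 0
        t = covered + 1 + gap
    return out


def generate(scenario: ScenarioConfig) -> tuple[ClaimsDataset, pd.DataFrame]:
    """Generate a claims dataset plus its ground-truth table.

    Deterministic under ``scenario.seed``: repeated calls produce identical
    frames (and therefore byte-identical files through the writer).

    Returns ``(dataset, truth)`` where ``truth`` has one row per constructed
    member-year: ``member_id, fiscal_year, intended_status,
    intended_moa_category`` with status in ``new | long_term | neither |
    excluded:<reason>``.
    """
    rng = np.random.default_rng(scenario.seed)
    by_class, chain_pool = _class_pools()
    slack = scenario.chaining_slack_days
    fy_min, fy_max = min(scenario.fiscal_years), max(scenario.fiscal_years)
    enr_start = to_day(fiscal_year_start(fy_min)) - 800
    enr_end = to_day(fiscal_year_end(fy_max)) + 30

    # institution pool: at least two per specialty so decoys can overlap
    n_inst = max(6, scenario.n_members // 50)
    inst_specs = [s for s in ("psychiatry", "GP", "others") for _ in range(2)]
    specs = list(scenario.specialty_mix)
    probs = np.array([scenario.specialty_mix[s] for s in specs])
    inst_specs += [specs[i] for i in rng.choice(len(specs), size=max(0, n_inst - 6), p=probs)]
    em = _Emitter()
    inst_by_spec: dict[str, list[str]] = {"psychiatry": [], "GP": [], "others": []}
    for i, spec in enumerate(inst_specs):
        inst_id = f"I{i:04d}"
        if spec == "psychiatry":
            dept = "psychiatry"
            beds = int(rng.integers(0, 400)) if rng.random() < 0.5 else int(rng.integers(0, 20))
        elif spec == "GP":
            dept, beds = "other", int(rng.integers(0, 20))
        else:
            dept, beds = "other", int(rng.integers(20, 400))
        em.institutions.append((inst_id, dept, beds))
        inst_by_spec[spec].append(inst_id)

    arch_names = list(scenario.archetype_mix)
    arch_probs = np.array([scenario.archetype_mix[a] for a in arch_names])
    age_groups = list(scenario.age_distribution)
    age_probs = np.array([scenario.age_distribution[g] for g in age_groups])

    def draw_category(mix: dict[str, float]) -> list[str]:
        labels = list(mix)
        label = labels[int(rng.choice(len(labels), p=np.array([mix[l] for l in labels])))]
        return label.split("+"), label

    def pick(pool_list):
        return pool_list[int(rng.integers(0, len(pool_list)))]

    truth_rows = []
    decoy_counter = 0

    for i in range(scenario.n_members):
        member = f"M{i:06d}"
        rx_start = len(em.prescriptions)
        archetype = arch_names[int(rng.choice(len(arch_names), p=arch_probs))]
        fy = int(scenario.fiscal_years[int(rng.integers(0, len(scenario.fiscal_years)))])
        fy_s, fy_e = to_day(fiscal_year_start(fy)), to_day(fiscal_year_end(fy))
        sex = "male" if rng.random() < scenario.sex_split_male else "female"
        spec = specs[int(rng.choice(len(specs), p=probs))]
        inst = pick(inst_by_spec[spec])
        age_group = age_groups[int(rng.choice(len(age_groups), p=age_probs))]
        lo, hi = _AGE_BOUNDS[age_group]
        age = int(rng.integers(lo, hi + 1))
        member_enr = (enr_start, enr_end)
        comorbidity_prev = scenario.comorbidity_prevalence_new

        if archetype == "incident_starter":
            index_day = int(rng.integers(fy_s, fy_e + 1))
            classes, label = draw_category(scenario.moa_mix_new)
            for cls in classes:
                entry = pick(by_class[cls])
                em.rx(member, index_day, entry, _supply(rng, entry, scenario.days_supplied_choices), inst)
            status = "new"

        elif archetype == "persistent_user":
            comorbidity_prev = scenario.comorbidity_prevalence_longterm
            classes, label = draw_category(scenario.moa_mix_longterm)
            back = int(rng.integers(200, 321))
            dur = int(rng.integers(30, 180))
            schedule = _chain_dates(rng, fy_s - back, fy_s + dur, slack)
            for cls in classes:
                entry = pick(chain_pool[cls])
                for day, supply in schedule:
                    em.rx(member, day, entry, supply, inst)
            index_day = min(d for d, _ in schedule if d >= fy_s)
            status = "long_term"

        elif archetype == "switcher":
            comorbidity_prev = scenario.comorbidity_prevalence_longterm
            cls_a, cls_b = rng.choice(["BZD", "Z_DRUG", "MRA", "ORA"], size=2, replace=False)
            label = str(cls_b)
            b = int(rng.integers(40, 101))
            b_start = fy_s - b
            # duration >= 30 guarantees a claim date on or after the FY start
            sched_b = _chain_dates(rng, b_start, fy_s + int(rng.integers(30, 90)), min(slack, 15))
            entry_b = pick(chain_pool[str(cls_b)])
            for day, supply in sched_b:
                em.rx(member, day, entry_b, supply, inst)
            span_a = int(rng.integers(60, 151))
            sched_a = [(d, s) for d, s in _chain_dates(rng, b_start - span_a, b_start - 1, min(slack, 15))
                       if d + s - 1 < b_start]
            entry_a = pick(chain_pool[str(cls_a)])
            for day, supply in sched_a:
                em.rx(member, day, entry_a, supply, inst)
            index_day = min(d for d, _ in sched_b if d >= fy_s)
            status = "neither"

        elif archetype == "intermittent_user":
            comorbidity_prev = scenario.comorbidity_prevalence_longterm
            k = int(rng.integers(200, 291))
            u = int(rng.integers(0, 61))
            index_day = fy_s + u
            classes, label = draw_category(scenario.moa_mix_new)
            early_entry = pick(by_class[classes[0]])
            em.rx(member, fy_s - k, early_entry,
                  _supply(rng, early_entry, scenario.days_supplied_choices), inst)
            for cls in classes:
                entry = pick(by_class[cls])
                em.rx(member, index_day, entry, _supply(rng, entry, scenario.days_supplied_choices), inst)
            status = "neither"

        else:  # ineligible_decoy
            kind = DECOY_KINDS[decoy_counter % len(DECOY_KINDS)]
            decoy_counter += 1
            index_day = int(rng.integers(fy_s, fy_e + 1))
            classes, label = draw_category(scenario.moa_mix_new)
            entry = pick(by_class[classes[0]])
            supply = _supply(rng, entry, scenario.days_supplied_choices)
            if kind == "no_insomnia_dx":
                em.rx(member, index_day, entry, supply, inst, with_dx=False)
            elif kind == "age_out_of_range":
                em.rx(member, index_day, entry, supply, inst)
                age = 19 if rng.random() < 0.5 else int(rng.integers(75, 81))
            elif kind == "insufficient_enrollment":
                em.rx(member, index_day, entry, supply, inst)
                member_enr = (index_day - int(rng.integers(60, 300)), enr_end)
            elif kind == "narcolepsy":
                em.rx(member, index_day, entry, supply, inst)
                em.dx(member, index_day, "G474")
            elif kind == "inpatient_at_index":
                em.rx(member, index_day, entry, supply, inst)
                em.dx(member, index_day, "G470", setting="inpatient")
            elif kind == "prn_only_at_index":
                em.rx(member, index_day, entry, supply, inst, prn=True)
            else:  # multi_prescriber_overlap_at_index
                em.rx(member, index_day, entry, supply, inst)
                other_specs = [s for s in specs if inst_by_spec[s] and
                               (s != spec or len(inst_by_spec[s]) > 1)]
                inst2 = pick([x for x in inst_by_spec[pick(other_specs)] if x != inst])
                em.rx(member, index_day, entry, supply, inst2)
            status = f"excluded:{kind}"

        # optional contamination of non-decoy members (robustness scenarios)
        if archetype != "ineligible_decoy":
            u01 = rng.random()
            if u01 < scenario.prn_rate:
                for j in range(rx_start, len(em.prescriptions)):
                    row = em.prescriptions[j]
                    if row[1] == index_day:
                        em.prescriptions[j] = row[:5] + (True,) + row[6:]
                status = "excluded:prn_only_at_index"
            elif u01 < scenario.prn_rate + scenario.multi_prescriber_rate:
                entry = pick(by_class["BZD"])
                inst2 = pick([x for s2 in specs for x in inst_by_spec[s2] if x != inst])
                em.rx(member, index_day, entry, _supply(rng, entry, scenario.days_supplied_choices), inst2)
                status = "excluded:multi_prescriber_overlap_at_index"
                label = ""  # index-day category no longer the planted one
            elif u01 < scenario.prn_rate + scenario.multi_prescriber_rate + scenario.narcolepsy_rate:
                em.dx(member, index_day - int(rng.integers(0, 300)), "G474")
                status = "excluded:narcolepsy"

        # demographics anchored at the index date
        r = int(rng.integers(0, 12))
        months = (from_day(index_day).year * 12 + from_day(index_day).month - 1) - (12 * age + r)
        birth = f"{months // 12:04d}-{months % 12 + 1:02d}"
        em.members.append((member, birth, sex))
        em.enrollment.append((member, member_enr[0], member_enr[1]))

        # baseline comorbidity codes
        for name in COMORBIDITY_NAMES:
            if rng.random() < comorbidity_prev.get(name, 0.0):
                code = _COMORBIDITY_CODES[name][int(rng.integers(0, len(_COMORBIDITY_CODES[name])))]
                em.dx(member, index_day - int(rng.integers(1, 360)), code)

        truth_rows.append((member, fy, status, label))

    def day_col(values):
        return pd.to_datetime(pd.Series(values, dtype="int64"), unit="D")

    members = pd.DataFrame(em.members, columns=["member_id", "birth_year_month", "sex"])
    enrollment = pd.DataFrame(em.enrollment, columns=["member_id", "start_date", "end_date"])
    enrollment["start_date"] = day_col(enrollment["start_date"])
    enrollment["end_date"] = day_col(enrollment["end_date"])
    diagnoses = pd.DataFrame(em.diagnoses, columns=["member_id", "claim_date", "icd10_code", "setting"])
    diagnoses["claim_date"] = day_col(diagnoses["claim_date"])
    prescriptions = pd.DataFrame(
        em.prescriptions,
        columns=["member_id", "dispense_date", "generic_name", "days_supplied",
                 "bedtime_flag", "prn_flag", "institution_id", "setting"],
    )
    prescriptions["dispense_date"] = day_col(prescriptions["dispense_date"])
    institutions = pd.DataFrame(em.institutions, columns=["institution_id", "primary_department", "n_beds"])

    dataset = ClaimsDataset(
        members=members,
        enrollment=enrollment,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        institutions=institutions,
        source={"scenario_seed": scenario.seed},
    ).validate()
    truth = pd.DataFrame(
        truth_rows, columns=["member_id", "fiscal_year", "intended_status", "intended_moa_category"]
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Recovery reporting
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Intended-vs-assigned cross-tabulations on the ground-truth member-years."""

    status_confusion: pd.DataFrame
    moa_confusion: pd.DataFrame
    n_status_mismatch: int
    n_moa_mismatch: int

    @property
    def exact(self) -> bool:
        return self.n_status_mismatch == 0 and self.n_moa_mismatch == 0


def _assigned_status(row) -> str:
    if pd.isna(row["status"]):
        return "no_decision"
    if row["status"] == "included_new":
        return "new"
    if row["status"] == "included_long_term":
        return "long_term"
    reasons = str(row["reason_codes"]).split("|")
    if reasons == ["neither_user_type"]:
        return "neither"
    return f"excluded:{reasons[0]}"


def recovery_report(truth: pd.DataFrame, audit: pd.DataFrame, cohort: pd.DataFrame) -> RecoveryReport:
    """Compare planted labels with pipeline assignments.

    Joins on the ground-truth (member, fiscal year) keys; exact agreement is
    expected when the pipeline grace period matches the generator's chaining
    slack.  ``moa_confusion`` covers the included member-years only.
    """
    if truth.empty:
        empty = pd.DataFrame()
        return RecoveryReport(empty, empty, 0, 0)
    merged = truth.merge(audit, on=["member_id", "fiscal_year"], how="left")
    merged["assigned"] = merged.apply(_assigned_status, axis=1)
    status_confusion = pd.crosstab(merged["intended_status"], merged["assigned"])
    n_status = int((merged["intended_status"] != merged["assigned"]).sum())

    included = merged[merged["intended_status"].isin(["new", "long_term"])]
    moa = included.merge(
        cohort[["member_id", "fiscal_year", "moa_label"]], on=["member_id", "fiscal_year"], how="left"
    )
    moa["moa_label"] = moa["moa_label"].fillna("(absent)")
    moa_confusion = pd.crosstab(moa["intended_moa_category"], moa["moa_label"])
    n_moa = int((moa["intended_moa_category"] != moa["moa_label"]).sum())
    return RecoveryReport(status_confusion, moa_confusion, n_status, n_moa)
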