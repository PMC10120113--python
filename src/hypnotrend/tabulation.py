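"""Index-date categorisation and descriptive tables with 95% confidence intervals.

Covers the analysis layer of the pipeline: the mechanism-of-action (MOA)
category a patient holds at the index date (single class vs a "multiple"
combination), the within-BZD duration-type breakdown, psychiatric comorbidity
flagging from baseline ICD-10 codes, and the yearly trend / pooled pattern
tables, each cell a count with a two-sided 95% CI on the proportion.

Category partitions are exact on counts: within one denominator group the
category counts always sum to the denominator; percentages are rounded (one
decimal, half away from zero) for display only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .drug_dictionary import DrugEntry, MOA_CLASSES, classification_index

__all__ = [
    "MoaCategory",
    "ProportionEstimate",
    "PatternTables",
    "moa_category_at_index",
    "moa_category_from_classes",
    "n_hypnotics_at_index",
    "n_hypnotics_bucket",
    "bzd_duration_category",
    "COMORBIDITY_NAMES",
    "comorbidity_flags",
    "flags_from_codes",
    "proportion_ci",
    "round_half_away",
    "trend_by_year",
    "pattern_distribution",
    "age_group_of",
    "AGE_GROUPS",
]

AGE_GROUPS = ("20-34", "35-49", "50-64", "65-74")

N_HYPNOTICS_BUCKETS = ("1", "2", "3", ">=4")

#: Psychiatric comorbidity categories, flagged from baseline-window diagnoses.
#: Neurocognitive disorders are restricted to Alzheimer's disease (F00, G30);
#: "others" is the residual of F00-F99 outside the six named sets.
COMORBIDITY_NAMES = (
    "substance_use",
    "schizophrenia_spectrum",
    "bipolar",
    "depressive",
    "anxiety",
    "neurocognitive",
    "others",
)

_RANGED = {
    "substance_use": ("F10", "F19"),
    "schizophrenia_spectrum": ("F20", "F29"),
    "bipolar": ("F30", "F31"),
    "depressive": ("F32", "F33"),
    "anxiety": ("F40", "F42"),
}
_NEUROCOGNITIVE = {"F00", "G30"}


@dataclass(frozen=True)
class MoaCategory:
    """MOA category at the index date.

    All drugs of one class count as that single class (two different
    benzodiazepines are still "single BZD"); ``multiple`` means >= 2 distinct
    classes on the index day.  ``combo_label`` lists classes in the fixed
    order BZD, Z_DRUG, MRA, ORA, OTHER joined by "+".
    """

    kind: str  # "single" | "multiple"
    classes: frozenset[str]
    combo_label: str


def _canonical_label(classes: Iterable[str]) -> str:
    ordered = [c for c in MOA_CLASSES if c in set(classes)]
    return "+".join(ordered)


def moa_category_from_classes(classes: Iterable[str]) -> MoaCategory:
    cls = frozenset(classes)
    if not cls:
        raise ValueError("MOA category requires at least one class")
    unknown = cls - set(MOA_CLASSES)
    if unknown:
        raise ValueError(f"unknown MOA classes: {sorted(unknown)}")
    return MoaCategory(
        kind="single" if len(cls) == 1 else "multiple",
        classes=cls,
        combo_label=_canonical_label(cls),
    )


def moa_category_at_index(
    index_day_claims: pd.DataFrame, dictionary: Sequence[DrugEntry] | None = None
) -> MoaCategory:
    """Category from all bedtime hypnotic claims dispensed on the index date."""
    if index_day_claims.empty:
        raise ValueError("no index-day claims")
    index = classification_index(dictionary)
    classes = {
        index[str(name).strip().lower()].moa_class
        for name in index_day_claims["generic_name"]
    }
    return moa_category_from_classes(classes)


def n_hypnotics_at_index(index_day_claims: pd.DataFrame) -> int:
    """Distinct generic names on the index date (same generic from two
    institutions counts once)."""
    if index_day_claims.empty:
        raise ValueError("no index-day claims")
    return index_day_claims["generic_name"].astype(str).str.strip().str.lower().nunique()


def n_hypnotics_bucket(n: int) -> str:
    if n < 1:
        raise ValueError("n must be >= 1")
    return str(n) if n <= 3 else ">=4"


def bzd_duration_category(
    index_day_claims: pd.DataFrame, dictionary: Sequence[DrugEntry] | None = None
) -> str:
    """Duration type of the index-day BZD prescriptions.

    A single shared type maps to that type; mixing types (e.g. a short- plus
    an intermediate-acting BZD) maps to ``two_or_more_types``.  Only defined
    for members whose index category includes BZD.
    """
    index = classification_index(dictionary)
    types = {
        index[str(name).strip().lower()].duration_type
        for name in index_day_claims["generic_name"]
        if index[str(name).strip().lower()].moa_class == "BZD"
    }
    if not types:
        raise ValueError("no BZD claims on the index date")
    return types.pop() if len(types) == 1 else "two_or_more_types"


# ---------------------------------------------------------------------------
# Comorbidity flagging
# ---------------------------------------------------------------------------

def _category3(code: str) -> str:
    return str(code).strip().upper()[:3]


def flags_from_codes(codes: Iterable[str]) -> dict[str, bool]:
    """Comorbidity flags from a collection of ICD-10 codes (non-exclusive)."""
    flags = {name: False for name in COMORBIDITY_NAMES}
    for code in codes:
        cat = _category3(code)
        named = False
        for name, (lo, hi) in _RANGED.items():
            if lo <= cat <= hi:
                flags[name] = True
                named = True
        if cat in _NEUROCOGNITIVE:
            flags["neurocognitive"] = True
            named = True
        if cat.startswith("F") and not named:
            flags["others"] = True
    return flags


def comorbidity_flags(
    member_id: str,
    baseline_start,
    baseline_end,
    diagnoses: pd.DataFrame,
) -> dict[str, bool]:
    """Flags from a member's diagnosis claims inside [baseline_start, baseline_end]."""
    sel = diagnoses[
        (diagnoses["member_id"] == member_id)
        & (diagnoses["claim_date"] >= pd.Timestamp(baseline_start))
        & (diagnoses["claim_date"] <= pd.Timestamp(baseline_end))
    ]
    return flags_from_codes(sel["icd10_code"])


# ---------------------------------------------------------------------------
# Proportions and confidence intervals
# ---------------------------------------------------------------------------

def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for percentages)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ProportionEstimate:
    """Count/denominator with percent point estimate and two-sided 95% CI.

    All fields are on the percent scale and unrounded; use :meth:`formatted`
    for the display convention (one decimal, half away from zero).
    """

    count: int
    denominator: int
    pct: float
    ci_low: float
    ci_high: float

    def formatted(self) -> str:
        return (
            f"{self.count} ({round_half_away(self.pct):.1f}%) "
            f"[{round_half_away(self.ci_low):.1f}-{round_half_away(self.ci_high):.1f}]"
        )


def proportion_ci(count: int, denominator: int, method: str = "wald") -> ProportionEstimate:
    """95% CI on a proportion, Wald (default) or Wilson score, clipped to [0, 100].

    Wald is the normal approximation p-hat +/- 1.96 sqrt(p-hat(1-p-hat)/n); at
    the cohort sizes this pipeline reports the Wilson interval is numerically
    indistinguishable, but both are offered.
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= count <= denominator:
        raise ValueError("count must be in [0, denominator]")
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r} (expected 'wald' or 'wilson')")
    low, high = proportion_confint(count, denominator, alpha=0.05, method=sm_method)
    low = min(max(float(low), 0.0), 1.0)
    high = min(max(float(high), 0.0), 1.0)
    return ProportionEstimate(
        count=int(count),
        denominator=int(denominator),
        pct=100.0 * count / denominator,
        ci_low=100.0 * low,
        ci_high=100.0 * high,
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

MOA_CATEGORY_LEVELS = tuple(MOA_CLASSES) + ("multiple",)


def _category_column(cohort: pd.DataFrame) -> pd.Series:
    return pd.Series(
        np.where(cohort["moa_kind"] == "multiple", "multiple", cohort["moa_label"]),
        index=cohort.index,
    )


def _distribution(
    values: pd.Series,
    categories: Sequence[str],
    ci_method: str,
) -> pd.DataFrame:
    """One row per category: count, denominator, pct, ci_low, ci_high.

    An empty denominator yields rows with denominator 0 and NaN estimates
    (flagged, never silently dropped).
    """
    denom = len(values)
    counts = values.value_counts()
    rows = []
    for cat in categories:
        n = int(counts.get(cat, 0))
        if denom == 0:
            rows.append((cat, 0, 0, np.nan, np.nan, np.nan))
        else:
            est = proportion_ci(n, denom, ci_method)
            rows.append((cat, n, denom, est.pct, est.ci_low, est.ci_high))
    return pd.DataFrame(rows, columns=["category", "count", "denominator", "pct", "ci_low", "ci_high"])


def trend_by_year(
    cohort: pd.DataFrame,
    user_type: str,
    strata: str | None = None,
    fiscal_years: Sequence[int] | None = None,
    ci_method: str = "wald",
) -> pd.DataFrame:
    """Yearly MOA-category distribution for one user type.

    One row per fiscal year (x stratum level, if ``strata`` names a cohort
    column) x category; the denominator is the number of cohort members of
    that user type in that year (and stratum).  Categories are the five
    single classes plus ``multiple``.
    """
    sel = cohort[cohort["user_type"] == user_type]
    if fiscal_years is None:
        fiscal_years = sorted(sel["fiscal_year"].unique())
    out = []
    for fy in fiscal_years:
        ysel = sel[sel["fiscal_year"] == fy]
        groups = [(None, ysel)] if strata is None else list(ysel.groupby(strata, observed=True))
        for level, grp in groups:
            dist = _distribution(_category_column(grp), MOA_CATEGORY_LEVELS, ci_method)
            dist.insert(0, "fiscal_year", fy)
            if strata is not None:
                dist.insert(1, strata, level)
            out.append(dist)
    if not out:
        cols = ["fiscal_year"] + ([strata] if strata else []) + ["category", "count", "denominator", "pct", "ci_low", "ci_high"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


@dataclass
class PatternTables:
    """Pooled-window pattern analysis output.

    ``moa``: top-level MOA-category distribution (denominator: all cohort
    member-years of the user type in the window -- a member indexed in both
    pooled years contributes twice).
    ``bzd_duration``: within-BZD duration types; the denominator is every
    member whose index category includes BZD, whether alone or in a
    combination.
    ``multi_combo``: combination labels among multiple-MOA members.
    ``segmented``: optional two-way breakdowns keyed by
    ("comorbidity", split_column).
    """

    user_type: str
    window: tuple[int, ...]
    moa: pd.DataFrame
    bzd_duration: pd.DataFrame
    multi_combo: pd.DataFrame
    n_hypnotics: pd.DataFrame
    segmented: dict[tuple[str, str], pd.DataFrame]


BZD_DURATION_LEVELS = ("long", "intermediate", "short", "ultrashort", "two_or_more_types")


def pattern_distribution(
    cohort: pd.DataFrame,
    user_type: str,
    window: Sequence[int] = (2018, 2019),
    segments: Sequence[str] = (),
    ci_method: str = "wald",
) -> PatternTables:
    """Pooled prescription-pattern distributions over a fiscal-year window.

    ``segments`` names cohort columns (e.g. ``age_group``, ``sex``) for the
    comorbidity x segment breakdowns: within each comorbidity flag and segment
    level, the MOA-category distribution of flagged members.
    """
    if len(window) == 0:
        raise ValueError("window must contain at least one fiscal year")
    sel = cohort[(cohort["user_type"] == user_type) & cohort["fiscal_year"].isin(list(window))]
    moa = _distribution(_category_column(sel), MOA_CATEGORY_LEVELS, ci_method)

    has_bzd = sel["moa_label"].str.split("+").map(lambda cs: "BZD" in cs)
    bzd = sel[has_bzd]
    bzd_duration = _distribution(bzd["bzd_duration"], BZD_DURATION_LEVELS, ci_method)

    multi = sel[sel["moa_kind"] == "multiple"]
    combo_levels = sorted(multi["moa_label"].unique(), key=lambda s: (s.count("+"), s))
    multi_combo = _distribution(multi["moa_label"], combo_levels, ci_method)

    nh = _distribution(
        sel["n_hypnotics"].map(n_hypnotics_bucket) if len(sel) else pd.Series(dtype=object),
        N_HYPNOTICS_BUCKETS,
        ci_method,
    )

    segmented: dict[tuple[str, str], pd.DataFrame] = {}
    for split in segments:
        parts = []
        for name in COMORBIDITY_NAMES:
            flagged = sel[sel[f"cm_{name}"]]
            for level, grp in flagged.groupby(split, observed=True):
                dist = _distribution(_category_column(grp), MOA_CATEGORY_LEVELS, ci_method)
                dist.insert(0, "comorbidity", name)
                dist.insert(1, split, level)
                parts.append(dist)
        cols = ["comorbidity", split, "category", "count", "denominator", "pct", "ci_low", "ci_high"]
        segmented[("comorbidity", split)] = (
            pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=cols)
        )

    return PatternTables(
        user_type=user_type,
        window=tuple(window),
        moa=moa,
        bzd_duration=bzd_duration,
        multi_combo=multi_combo,
        n_hypnotics=nh,
        segmented=segmented,
    )


def age_group_of(age: int) -> str:
    if 20 <= age <= 34:
        return "20-34"
    if 35 <= age <= 49:
        return "35-49"
    if 50 <= age <= 64:
        return "50-64"
    if 65 <= age <= 74:
        return "65-74"
    raise ValueError(f"age {age} outside the 20-74 analysis range")
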