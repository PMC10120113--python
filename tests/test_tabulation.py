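import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hypnotrend.tabulation import (
    bzd_duration_category,
    flags_from_codes,
    moa_category_at_index,
    n_hypnotics_at_index,
    n_hypnotics_bucket,
    pattern_distribution,
    proportion_ci,
    round_half_away,
    trend_by_year,
)

from conftest import make_dataset, member, rx


def _claims(*names):
    ds = make_dataset(
        members=[member("M1")],
        prescriptions=[rx("M1", "2018-05-10", n, 30) for n in names],
    )
    return ds.prescriptions


def test_moa_category_single_vs_multiple():
    single = moa_category_at_index(_claims("Brotizolam"))
    assert (single.kind, single.combo_label) == ("single", "BZD")
    combo = moa_category_at_index(_claims("Brotizolam", "Zolpidem tartrate"))
    assert (combo.kind, combo.combo_label) == ("multiple", "BZD+Z_DRUG")
    # two benzodiazepines are one MOA regardless of type
    two_bzd = moa_category_at_index(_claims("Brotizolam", "Estazolam"))
    assert (two_bzd.kind, two_bzd.combo_label) == ("single", "BZD")
    # canonical class order in the label
    reordered = moa_category_at_index(_claims("Suvorexant", "Zopiclone"))
    assert reordered.combo_label == "Z_DRUG+ORA"


def test_n_hypnotics_counts_distinct_generics():
    assert n_hypnotics_at_index(_claims("Brotizolam")) == 1
    dupe = make_dataset(
        members=[member("M1")],
        prescriptions=[
            rx("M1", "2018-05-10", "Brotizolam", 30, inst="I1"),
            rx("M1", "2018-05-10", "Brotizolam", 30, inst="I1"),
        ],
    ).prescriptions
    assert n_hypnotics_at_index(dupe) == 1
    assert n_hypnotics_at_index(_claims("Brotizolam", "Zopiclone", "Ramelteon", "Suvorexant")) == 4
    assert n_hypnotics_bucket(4) == ">=4"
    assert [n_hypnotics_bucket(k) for k in (1, 2, 3)] == ["1", "2", "3"]


def test_bzd_duration_category():
    assert bzd_duration_category(_claims("Triazolam")) == "ultrashort"
    assert bzd_duration_category(_claims("Brotizolam", "Estazolam")) == "two_or_more_types"
    assert bzd_duration_category(_claims("Brotizolam", "Etizolam")) == "short"
    # non-BZD claims on the same day are ignored
    assert bzd_duration_category(_claims("Brotizolam", "Suvorexant")) == "short"


@pytest.mark.parametrize(
    "code, expected_true",
    [
        ("F32", {"depressive"}),
        ("F41", {"anxiety"}),
        ("F43", {"others"}),          # outside F40-F42
        ("F03", {"others"}),          # dementia not Alzheimer's
        ("F00", {"neurocognitive"}),
        ("G30", {"neurocognitive"}),
        ("F10", {"substance_use"}),
        ("F199", {"substance_use"}),  # 4-character code, category prefix
        ("G470", set()),              # not a psychiatric chapter code
    ],
)
def test_comorbidity_ranges(code, expected_true):
    flags = flags_from_codes([code])
    assert {k for k, v in flags.items() if v} == expected_true


def test_comorbidity_flags_are_non_exclusive():
    flags = flags_from_codes(["F32", "F41", "F99"])
    assert flags["depressive"] and flags["anxiety"] and flags["others"]


def test_wald_ci_matches_closed_form():
    """The Wald interval equals p-hat +/- 1.96*sqrt(p-hat(1-p-hat)/n) to 1e-9."""
    z = 1.959963984540054
    for count, denom in [(29892, 55263), (1, 10), (999, 1000), (500, 1000)]:
        est = proportion_ci(count, denom, "wald")
        p = count / denom
        se = math.sqrt(p * (1 - p) / denom)
        assert est.ci_low == pytest.approx(max(0.0, 100 * (p - z * se)), abs=1e-9)
        assert est.ci_high == pytest.approx(min(100.0, 100 * (p + z * se)), abs=1e-9)
        assert est.pct == pytest.approx(100 * p, abs=1e-12)


def test_ci_clipping_and_symmetry():
    zero = proportion_ci(0, 10, "wald")
    assert zero.pct == 0.0 and zero.ci_low == 0.0
    full = proportion_ci(10, 10, "wald")
    assert full.ci_high == 100.0
    half = proportion_ci(500, 1000, "wald")
    assert half.pct == 50.0
    assert half.ci_high - 50.0 == pytest.approx(50.0 - half.ci_low, abs=1e-9)
    # Wilson lower bound dominates Wald at count 0
    assert proportion_ci(0, 10, "wilson").ci_low >= zero.ci_low


@given(count=st.integers(0, 500), denom=st.integers(1, 500))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_proportion_estimate_invariants(count, denom):
    count = min(count, denom)
    for method in ("wald", "wilson"):
        est = proportion_ci(count, denom, method)
        assert 0.0 <= est.ci_low <= est.pct + 1e-9
        assert est.pct - 1e-9 <= est.ci_high <= 100.0
        assert est.pct == pytest.approx(100 * count / denom, abs=1e-12)


def test_round_half_away():
    assert round_half_away(54.05) == 54.1
    assert round_half_away(54.04) == 54.0
    assert round_half_away(-0.05) == -0.1


def _toy_cohort():
    rows = []
    spec = [
        # fy, user_type, kind, label, duration, sex, nh
        (2018, "new", "single", "BZD", "short", "male", 1),
        (2018, "new", "single", "Z_DRUG", "", "female", 1),
        (2018, "new", "multiple", "BZD+Z_DRUG", "short", "male", 2),
        (2019, "new", "single", "BZD", "ultrashort", "female", 1),
        (2019, "long_term", "single", "BZD", "two_or_more_types", "male", 2),
        (2019, "long_term", "multiple", "BZD+ORA", "short", "female", 3),
    ]
    for i, (fy, ut, kind, label, dur, sex, nh) in enumerate(spec):
        rows.append(
            {
                "member_id": f"M{i}", "fiscal_year": fy, "user_type": ut,
                "moa_kind": kind, "moa_label": label, "bzd_duration": dur,
                "sex": sex, "age_group": "35-49", "specialty": "GP",
                "setting": "clinic", "n_hypnotics": nh,
                "cm_depressive": i % 2 == 0,
            }
        )
    frame = pd.DataFrame(rows)
    for name in ("substance_use", "schizophrenia_spectrum", "bipolar", "anxiety",
                 "neurocognitive", "others"):
        frame[f"cm_{name}"] = False
    return frame


def test_trend_partitions_and_empty_years():
    cohort = _toy_cohort()
    trend = trend_by_year(cohort, "new", fiscal_years=[2018, 2019, 2020])
    for fy, expected_denom in ((2018, 3), (2019, 1), (2020, 0)):
        year = trend[trend["fiscal_year"] == fy]
        assert year["count"].sum() == expected_denom
        if expected_denom:
            assert (year["denominator"] == expected_denom).all()
            assert year["pct"].sum() == pytest.approx(100.0)
        else:
            assert year["pct"].isna().all()  # undefined estimates flagged
    y2018 = trend[trend["fiscal_year"] == 2018].set_index("category")["count"]
    assert y2018["BZD"] == 1 and y2018["Z_DRUG"] == 1 and y2018["multiple"] == 1


def test_trend_stratified_counts_sum_to_unstratified():
    cohort = _toy_cohort()
    flat = trend_by_year(cohort, "new")
    by_sex = trend_by_year(cohort, "new", strata="sex")
    merged = by_sex.groupby(["fiscal_year", "category"])["count"].sum()
    for row in flat.itertuples():
        assert merged.get((row.fiscal_year, row.category), 0) == row.count


def test_pattern_nested_denominators():
    cohort = _toy_cohort()
    pat = pattern_distribution(cohort, "new", window=(2018, 2019), segments=("sex",))
    assert pat.moa["count"].sum() == 4
    # BZD-duration denominator = everyone prescribed a BZD (incl. combinations)
    assert (pat.bzd_duration["denominator"] == 3).all()
    assert pat.bzd_duration["count"].sum() == 3
    assert (pat.multi_combo["denominator"] == 1).all()
    assert pat.n_hypnotics["count"].sum() == 4
    seg = pat.segmented[("comorbidity", "sex")]
    dep = seg[seg["comorbidity"] == "depressive"]
    assert dep["count"].sum() == 2  # the two flagged new member-years


def test_pooled_window_counts_member_years_not_members():
    """A member indexed in both pooled years contributes twice."""
    cohort = _toy_cohort()
    twice = cohort[cohort["user_type"] == "new"].copy()
    twice["member_id"] = "M_same"
    pat = pattern_distribution(twice, "new", window=(2018, 2019))
    assert pat.moa["denominator"].iloc[0] == 4
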