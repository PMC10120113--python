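import datetime as dt

import pandas as pd
import pytest

from hypnotrend.claims_model import ClaimsDataset, TABLE_COLUMNS


def make_dataset(members=(), enrollment=(), diagnoses=(), prescriptions=(), institutions=None):
    """Build a typed ClaimsDataset from plain row tuples (dates as ISO strings).

    ``institutions`` defaults to one GP clinic "I1" so prescription rows can
    reference it without ceremony.
    """
    if institutions is None:
        institutions = [("I1", "other", 5)]
    frames = {}
    for name, rows in (
        ("members", members),
        ("enrollment", enrollment),
        ("diagnoses", diagnoses),
        ("prescriptions", prescriptions),
        ("institutions", institutions),
    ):
        cols = list(TABLE_COLUMNS[name])
        frame = pd.DataFrame(list(rows), columns=cols)
        for col in cols:
            if col.endswith("_date"):
                frame[col] = pd.to_datetime(frame[col], format="%Y-%m-%d")
        if name == "institutions":
            frame["n_beds"] = frame["n_beds"].astype("int64")
        if name == "prescriptions" and len(frame):
            frame["days_supplied"] = frame["days_supplied"].astype("int64")
            frame["bedtime_flag"] = frame["bedtime_flag"].astype(bool)
            frame["prn_flag"] = frame["prn_flag"].astype(bool)
        frames[name] = frame
    return ClaimsDataset(**frames)


def rx(member, date, generic, days, *, bedtime=True, prn=False, inst="I1", setting="outpatient"):
    return (member, date, generic, days, bedtime, prn, inst, setting)


def member(mid, birth="1980-06", sex="male"):
    return (mid, birth, sex)


def enrol(mid, start, end):
    return (mid, start, end)


def dx(mid, date, code="G470", setting="outpatient"):
    return (mid, date, code, setting)


@pytest.fixture
def simple_member_dataset():
    """One member with an insomnia diagnosis, long enrolment and one claim."""
    return make_dataset(
        members=[member("M1")],
        enrollment=[enrol("M1", "2017-01-01", "2020-03-31")],
        diagnoses=[dx("M1", "2018-05-10")],
        prescriptions=[rx("M1", "2018-05-10", "Brotizolam", 30)],
    )


@pytest.fixture
def day():
    def _day(iso: str) -> dt.date:
        return dt.date.fromisoformat(iso)

    return _day
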