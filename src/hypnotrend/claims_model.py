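"""Typed claims-data model, delimited-table I/O, and interval utilities.

The whole pipeline exchanges one :class:`ClaimsDataset` holding five pandas
tables (members, enrollment, diagnoses, prescriptions, institutions).  All
dates are day-granular calendar dates (ISO 8601 on disk); every interval in
this package is closed, ``[start, end]``, inclusive of both endpoints, so
"days covered" counts are integral.

Downstream modules never re-read files: they accept only the validated
dataset object produced here.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClaimsSchemaError",
    "MemberRecord",
    "EnrollmentInterval",
    "DiagnosisClaim",
    "PrescriptionClaim",
    "InstitutionRecord",
    "ClaimsDataset",
    "read_claims_tables",
    "write_claims_tables",
    "merge_enrollment",
    "TABLE_NAMES",
    "TABLE_COLUMNS",
]

SEX_VALUES = ("male", "female")
SETTING_VALUES = ("outpatient", "inpatient")
DEPARTMENT_VALUES = ("psychiatry", "other")

#: ICD-10 category code: one letter + 2-3 digits, e.g. "F32", "G470".
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2,3}$")
_YM_PATTERN = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")

TABLE_NAMES = ("members", "enrollment", "diagnoses", "prescriptions", "institutions")

TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "members": ("member_id", "birth_year_month", "sex"),
    "enrollment": ("member_id", "start_date", "end_date"),
    "diagnoses": ("member_id", "claim_date", "icd10_code", "setting"),
    "prescriptions": (
        "member_id",
        "dispense_date",
        "generic_name",
        "days_supplied",
        "bedtime_flag",
        "prn_flag",
        "institution_id",
        "setting",
    ),
    "institutions": ("institution_id", "primary_department", "n_beds"),
}

_EPOCH_ORDINAL = dt.date(1970, 1, 1).toordinal()


def to_day(d: dt.date) -> int:
    """Calendar date -> integer day number (days since 1970-01-01)."""
    return d.toordinal() - _EPOCH_ORDINAL


def from_day(n: int) -> dt.date:
    """Integer day number -> calendar date."""
    return dt.date.fromordinal(int(n) + _EPOCH_ORDINAL)


def series_to_day(s: pd.Series) -> np.ndarray:
    """datetime64 series -> int64 day numbers (NaT -> minimum int, caller guards)."""
    return s.to_numpy().astype("datetime64[D]").astype("int64")


class ClaimsSchemaError(ValueError):
    """A claims table failed validation.

    Carries the offending table/file, 1-based data row number (header = row 1,
    first data row = row 2) and field name so audit trails can point at the
    exact cell.
    """

    def __init__(self, message: str, *, table: str, row: int | None = None, column: str | None = None):
        self.table = table
        self.row = row
        self.column = column
        loc = table
        if row is not None:
            loc += f", row {row}"
        if column is not None:
            loc += f", column '{column}'"
        super().__init__(f"{loc}: {message}")


# ---------------------------------------------------------------------------
# Record types (the per-row schema; tables are stored as DataFrames)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MemberRecord:
    member_id: str
    birth_year_month: str  # "YYYY-MM"
    sex: str


@dataclass(frozen=True)
class EnrollmentInterval:
    member_id: str
    start_date: dt.date
    end_date: dt.date


@dataclass(frozen=True)
class DiagnosisClaim:
    member_id: str
    claim_date: dt.date
    icd10_code: str
    setting: str


@dataclass(frozen=True)
class PrescriptionClaim:
    """One dispensed prescription.

    The supply covers the closed interval
    ``[dispense_date, dispense_date + days_supplied - 1]``.
    A missing (unparseable-as-absent) dispense date is representable as None
    so the cohort stage can apply the missing-prescription-date exclusion.
    """

    member_id: str
    dispense_date: dt.date | None
    generic_name: str
    days_supplied: int
    bedtime_flag: bool
    prn_flag: bool
    institution_id: str
    setting: str


@dataclass(frozen=True)
class InstitutionRecord:
    institution_id: str
    primary_department: str
    n_beds: int


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class ClaimsDataset:
    """The five claims tables, validated and typed.

    Date columns are pandas datetime64[ns] (day precision); boolean flags are
    numpy bool; ``prescriptions.dispense_date`` may be NaT (missing date).
    """

    members: pd.DataFrame
    enrollment: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    institutions: pd.DataFrame
    source: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in TABLE_NAMES}

    def validate(self) -> "ClaimsDataset":
        for name in TABLE_NAMES:
            frame = getattr(self, name)
            missing = [c for c in TABLE_COLUMNS[name] if c not in frame.columns]
            if missing:
                raise ClaimsSchemaError(f"missing columns {missing}", table=name)
        _validate_members(self.members)
        _validate_enrollment(self.enrollment)
        _validate_diagnoses(self.diagnoses)
        _validate_prescriptions(self.prescriptions)
        _validate_institutions(self.institutions)
        _validate_referential(self)
        return self


def _row_no(frame: pd.DataFrame, mask: np.ndarray | pd.Series) -> int:
    # +2: header is line 1, positional index 0 is line 2
    return int(np.flatnonzero(np.asarray(mask))[0]) + 2


def _check(frame: pd.DataFrame, bad: pd.Series, table: str, column: str, message: str) -> None:
    if bool(bad.any()):
        raise ClaimsSchemaError(message, table=table, row=_row_no(frame, bad), column=column)


def _validate_members(m: pd.DataFrame) -> None:
    _check(m, ~m["member_id"].astype(str).str.len().astype(bool), "members", "member_id", "empty member_id")
    _check(m, m["member_id"].duplicated(), "members", "member_id", "duplicate member_id")
    _check(
        m,
        ~m["birth_year_month"].astype(str).str.match(_YM_PATTERN),
        "members",
        "birth_year_month",
        "birth_year_month must be 'YYYY-MM'",
    )
    _check(m, ~m["sex"].isin(SEX_VALUES), "members", "sex", f"sex must be one of {SEX_VALUES}")


def _validate_enrollment(e: pd.DataFrame) -> None:
    _check(e, e["start_date"].isna(), "enrollment", "start_date", "unparseable or missing date")
    _check(e, e["end_date"].isna(), "enrollment", "end_date", "unparseable or missing date")
    _check(e, e["end_date"] < e["start_date"], "enrollment", "end_date", "end_date before start_date")


def _validate_diagnoses(d: pd.DataFrame) -> None:
    _check(d, d["claim_date"].isna(), "diagnoses", "claim_date", "unparseable or missing date")
    _check(
        d,
        ~d["icd10_code"].astype(str).str.match(ICD10_PATTERN),
        "diagnoses",
        "icd10_code",
        "ICD-10 code must be a letter followed by 2-3 digits",
    )
    _check(d, ~d["setting"].isin(SETTING_VALUES), "diagnoses", "setting", f"setting must be one of {SETTING_VALUES}")


def _validate_prescriptions(p: pd.DataFrame) -> None:
    days = p["days_supplied"]
    _check(p, days.isna() | (days < 1), "prescriptions", "days_supplied", "days_supplied must be >= 1")
    _check(p, ~p["setting"].isin(SETTING_VALUES), "prescriptions", "setting", f"setting must be one of {SETTING_VALUES}")
    for col in ("bedtime_flag", "prn_flag"):
        if p[col].dtype != bool:
            _check(p, ~p[col].isin([True, False]), "prescriptions", col, "flag must be true/false")


def _validate_institutions(i: pd.DataFrame) -> None:
    _check(i, i["institution_id"].duplicated(), "institutions", "institution_id", "duplicate institution_id")
    _check(
        i,
        ~i["primary_department"].isin(DEPARTMENT_VALUES),
        "institutions",
        "primary_department",
        f"primary_department must be one of {DEPARTMENT_VALUES}",
    )
    _check(i, i["n_beds"].isna() | (i["n_beds"] < 0), "institutions", "n_beds", "n_beds must be >= 0")


def _validate_referential(ds: ClaimsDataset) -> None:
    members = set(ds.members["member_id"])
    for table in ("enrollment", "diagnoses", "prescriptions"):
        frame = getattr(ds, table)
        bad = ~frame["member_id"].isin(members)
        _check(frame, bad, table, "member_id", "member_id has no MemberRecord")
    institutions = set(ds.institutions["institution_id"])
    bad = ~ds.prescriptions["institution_id"].isin(institutions)
    _check(ds.prescriptions, bad, "prescriptions", "institution_id", "institution_id has no InstitutionRecord")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _parse_dates(frame: pd.DataFrame, table: str, column: str, allow_missing: bool = False) -> pd.Series:
    raw = frame[column].astype(str).str.strip()
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    blank = raw == ""
    bad = parsed.isna() & ~blank
    _check(frame, bad, table, column, "unparseable date (expected YYYY-MM-DD)")
    if not allow_missing:
        _check(frame, blank, table, column, "missing date")
    return parsed


def _parse_int(frame: pd.DataFrame, table: str, column: str) -> pd.Series:
    parsed = pd.to_numeric(frame[column], errors="coerce")
    bad = parsed.isna() | (parsed != parsed.round())
    _check(frame, bad, table, column, "not an integer")
    return parsed.astype("int64")


def _parse_bool(frame: pd.DataFrame, table: str, column: str) -> pd.Series:
    raw = frame[column].astype(str).str.strip().str.lower()
    bad = ~raw.isin(["true", "false"])
    _check(frame, bad, table, column, "flag must be 'true' or 'false'")
    return raw == "true"


def read_claims_tables(paths: Mapping[str, str | Path] | str | Path) -> ClaimsDataset:
    """Read, type and validate the five claims tables.

    Parameters
    ----------
    paths
        Either a directory containing ``members.csv``, ``enrollment.csv``,
        ``diagnoses.csv``, ``prescriptions.csv``, ``institutions.csv``
        (``.tsv`` is honoured and switches the delimiter to tab), or a mapping
        from table name to file path.

    Raises
    ------
    ClaimsSchemaError
        On a missing file, missing column, unparseable value or broken
        referential integrity, naming the table, row and column.
    """
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        resolved: dict[str, Path] = {}
        for name in TABLE_NAMES:
            for ext in (".csv", ".tsv"):
                cand = root / f"{name}{ext}"
                if cand.exists():
                    resolved[name] = cand
                    break
            else:
                raise ClaimsSchemaError(f"file not found under {root}", table=name)
        paths = resolved
    frames: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        if name not in paths:
            raise ClaimsSchemaError("no path given", table=name)
        path = Path(paths[name])
        if not path.exists():
            raise ClaimsSchemaError(f"file not found: {path}", table=name)
        raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
        missing = [c for c in TABLE_COLUMNS[name] if c not in raw.columns]
        if missing:
            raise ClaimsSchemaError(f"missing columns {missing}", table=str(path))
        frames[name] = raw

    members = frames["members"].copy()
    enrollment = frames["enrollment"].copy()
    enrollment["start_date"] = _parse_dates(enrollment, "enrollment", "start_date")
    enrollment["end_date"] = _parse_dates(enrollment, "enrollment", "end_date")
    diagnoses = frames["diagnoses"].copy()
    diagnoses["claim_date"] = _parse_dates(diagnoses, "diagnoses", "claim_date")
    rx = frames["prescriptions"].copy()
    # an empty dispense_date is a *representable* missing value (exclusion rule
    # downstream); a malformed one is a schema error
    rx["dispense_date"] = _parse_dates(rx, "prescriptions", "dispense_date", allow_missing=True)
    rx["days_supplied"] = _parse_int(rx, "prescriptions", "days_supplied")
    rx["bedtime_flag"] = _parse_bool(rx, "prescriptions", "bedtime_flag")
    rx["prn_flag"] = _parse_bool(rx, "prescriptions", "prn_flag")
    institutions = frames["institutions"].copy()
    institutions["n_beds"] = _parse_int(institutions, "institutions", "n_beds")

    ds = ClaimsDataset(
        members=members,
        enrollment=enrollment,
        diagnoses=diagnoses,
        prescriptions=rx,
        institutions=institutions,
        source={name: str(paths[name]) for name in TABLE_NAMES},
    )
    return ds.validate()


def write_claims_tables(dataset: ClaimsDataset, directory: str | Path, sep: str = ",") -> dict[str, Path]:
    """Write the five tables as delimited UTF-8 text with a header row.

    Round-trips through :func:`read_claims_tables` are the identity.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if sep == "\t" else ".csv"
    out: dict[str, Path] = {}
    for name in TABLE_NAMES:
        frame = getattr(dataset, name)[list(TABLE_COLUMNS[name])].copy()
        for col in frame.columns:
            if pd.api.types.is_datetime64_any_dtype(frame[col]):
                frame[col] = frame[col].dt.strftime("%Y-%m-%d")
            elif frame[col].dtype == bool:
                frame[col] = np.where(frame[col], "true", "false")
        path = directory / f"{name}{ext}"
        frame.to_csv(path, sep=sep, index=False, lineterminator="\n")
        out[name] = path
    return out


# ---------------------------------------------------------------------------
# Interval merging
# ---------------------------------------------------------------------------

def merge_intervals_frame(
    frame: pd.DataFrame,
    keys: list[str],
    start_col: str,
    end_col: str,
    max_gap_days: int,
    count_col: str | None = None,
) -> pd.DataFrame:
    """Merge closed integer-day intervals within groups, bridging gaps <= max_gap_days.

    ``start_col``/``end_col`` must be int64 day numbers.  Two intervals merge
    iff the later start is <= earlier covered end + max_gap_days + 1 (i.e. the
    uncovered gap between them is at most ``max_gap_days`` days).
    """
    if frame.empty:
        cols = keys + [start_col, end_col] + ([count_col] if count_col else [])
        return pd.DataFrame(columns=cols)
    f = frame.sort_values(keys + [start_col, end_col], kind="mergesort").reset_index(drop=True)
    running_end = f.groupby(keys, sort=False)[end_col].cummax()
    prev_end = running_end.groupby([f[k] for k in keys], sort=False).shift()
    new_episode = prev_end.isna() | (f[start_col] > prev_end + max_gap_days + 1)
    episode_id = new_episode.cumsum()
    grouped = f.groupby(keys + [episode_id.rename("_eid")], sort=False)
    agg = grouped.agg(**{start_col: (start_col, "min"), end_col: (end_col, "max")})
    if count_col:
        agg[count_col] = grouped.size()
    return agg.reset_index().drop(columns="_eid")


def merge_enrollment(enrollment: pd.DataFrame, max_gap_days: int = 0) -> pd.DataFrame:
    """Merge enrolment intervals per member into disjoint, sorted spans.

    Gaps of at most ``max_gap_days`` uncovered days are bridged; the default 0
    treats only abutting or overlapping intervals as continuous (strict
    continuous-enrolment reading).  Returns columns
    ``member_id, start_date, end_date`` with datetime64 dates.
    """
    if max_gap_days < 0:
        raise ValueError("max_gap_days must be >= 0")
    work = enrollment[["member_id"]].copy()
    work["_s"] = series_to_day(enrollment["start_date"])
    work["_e"] = series_to_day(enrollment["end_date"])
    merged = merge_intervals_frame(work, ["member_id"], "_s", "_e", max_gap_days)
    out = pd.DataFrame(
        {
            "member_id": merged["member_id"],
            "start_date": pd.to_datetime(merged["_s"], unit="D"),
            "end_date": pd.to_datetime(merged["_e"], unit="D"),
        }
    )
    return out


def records_to_frame(records: Iterable, table: str) -> pd.DataFrame:
    """Build a table DataFrame from record dataclasses (convenience for tests)."""
    cols = TABLE_COLUMNS[table]
    rows = [[getattr(r, c) for c in cols] for r in records]
    frame = pd.DataFrame(rows, columns=list(cols))
    for col in cols:
        if col.endswith("_date"):
            frame[col] = pd.to_datetime(frame[col])
    return frame
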