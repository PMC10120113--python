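"""Continuous-coverage episode ("drug era") construction per MOA class.

A member's dated, supplied prescriptions are chained into coverage episodes
separately for each mechanism-of-action class.  Every claim covers the closed
interval ``[dispense_date, dispense_date + days_supplied - 1]``; a later claim
extends the running episode whenever its start is at most the covered end plus
``grace_days + 1`` (i.e. at most ``grace_days`` uncovered days separate them).
All generics of one class pool into a single stream -- switching between two
benzodiazepines never breaks a BZD episode.

Overlapping same-class claims (early refills) extend coverage by interval
union; supply is never stockpiled or shifted.  PRN-flagged claims contribute
to coverage (PRN status matters only at the cohort index date, not for
continuity).

The default grace period is 30 days: most formulary entries carry a 30-day
per-prescription cap, so one missed refill cycle is the conventional slack.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .claims_model import ClaimsDataset, from_day, series_to_day, merge_intervals_frame, to_day
from .drug_dictionary import DrugEntry, classification_index

__all__ = [
    "DEFAULT_GRACE_DAYS",
    "CoverageEpisode",
    "build_episodes",
    "episode_covering",
    "continuous_days_before",
    "episodes_to_dates",
]

DEFAULT_GRACE_DAYS = 30

EPISODE_COLUMNS = ("member_id", "moa_class", "start_day", "end_day", "n_claims")


@dataclass(frozen=True)
class CoverageEpisode:
    member_id: str
    moa_class: str
    start_date: dt.date
    end_date: dt.date
    n_claims: int


def classify_prescriptions(
    prescriptions: pd.DataFrame, dictionary: Sequence[DrugEntry] | None = None
) -> pd.DataFrame:
    """Attach ``moa_class`` (and ``duration_type``) columns via the formulary.

    Raises :class:`~hypnotrend.drug_dictionary.UnknownDrugError` on the first
    generic name outside the dictionary (pipeline default: abort).
    """
    index = classification_index(dictionary)
    out = prescriptions.copy()
    keys = out["generic_name"].astype(str).str.strip().str.lower()
    moa = keys.map({k: e.moa_class for k, e in index.items()})
    if moa.isna().any():
        from .drug_dictionary import UnknownDrugError

        bad = out.loc[moa.isna(), "generic_name"].iloc[0]
        raise UnknownDrugError(str(bad))
    out["moa_class"] = moa
    out["duration_type"] = keys.map({k: e.duration_type for k, e in index.items()})
    return out


def build_episodes(
    prescriptions: pd.DataFrame,
    dictionary: Sequence[DrugEntry] | None = None,
    grace_days: int = DEFAULT_GRACE_DAYS,
) -> pd.DataFrame:
    """Chain classified prescriptions into per-member, per-class episodes.

    Parameters
    ----------
    prescriptions
        Prescription claims (typically pre-filtered to bedtime outpatient
        hypnotics with a known dispense date).  Rows with a missing (NaT)
        dispense date are ignored here; the cohort stage excludes such members
        separately.
    grace_days
        Maximum uncovered gap, in days, bridged between successive claims.

    Returns
    -------
    DataFrame with columns ``member_id, moa_class, start_day, end_day,
    n_claims`` where the day columns are integer day numbers; use
    :func:`episodes_to_dates` for a calendar-dated view.  Episodes of one
    member and class are pairwise disjoint and separated by gaps >
    ``grace_days``; the result is independent of input row order.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be >= 0")
    rx = prescriptions
    if "moa_class" not in rx.columns:
        rx = classify_prescriptions(rx, dictionary)
    rx = rx[rx["dispense_date"].notna()]
    if rx.empty:
        return pd.DataFrame(columns=list(EPISODE_COLUMNS))
    work = pd.DataFrame(
        {
            "member_id": rx["member_id"].to_numpy(),
            "moa_class": rx["moa_class"].to_numpy(),
            "start_day": series_to_day(rx["dispense_date"]),
        }
    )
    work["end_day"] = work["start_day"] + rx["days_supplied"].to_numpy() - 1
    merged = merge_intervals_frame(
        work, ["member_id", "moa_class"], "start_day", "end_day", grace_days, count_col="n_claims"
    )
    return merged[list(EPISODE_COLUMNS)]


def episodes_to_dates(episodes: pd.DataFrame) -> pd.DataFrame:
    """Integer-day episode table -> audit-friendly calendar-dated table."""
    out = episodes.copy()
    out["start_date"] = pd.to_datetime(out.pop("start_day"), unit="D")
    out["end_date"] = pd.to_datetime(out.pop("end_day"), unit="D")
    return out[["member_id", "moa_class", "start_date", "end_date", "n_claims"]]


def episode_covering(
    episodes: pd.DataFrame,
    member_id: str,
    moa_class: str,
    date: dt.date,
) -> CoverageEpisode | None:
    """The unique episode of that member/class whose closed span contains date.

    Episodes from :func:`build_episodes` are disjoint within member x class,
    so at most one can match; returns ``None`` when the date is uncovered.
    """
    day = to_day(date)
    sel = episodes[
        (episodes["member_id"] == member_id)
        & (episodes["moa_class"] == moa_class)
        & (episodes["start_day"] <= day)
        & (episodes["end_day"] >= day)
    ]
    if sel.empty:
        return None
    if len(sel) > 1:  # disjointness invariant violated upstream
        raise ValueError(f"overlapping episodes for {member_id}/{moa_class} at {date}")
    row = sel.iloc[0]
    return CoverageEpisode(
        member_id=row["member_id"],
        moa_class=row["moa_class"],
        start_date=from_day(row["start_day"]),
        end_date=from_day(row["end_day"]),
        n_claims=int(row["n_claims"]),
    )


def continuous_days_before(episode: CoverageEpisode, date: dt.date) -> int:
    """Inclusive day count from episode start through ``date``.

    This is the quantity compared against the long-term-use threshold: an
    episode reaching back >= 180 days before the index date has
    ``continuous_days_before >= 181`` (the index day itself is counted).
    """
    if not (episode.start_date <= date <= episode.end_date):
        raise ValueError(f"date {date} outside episode [{episode.start_date}..{episode.end_date}]")
    return (date - episode.start_date).days + 1


def episodes_for_dataset(
    dataset: ClaimsDataset,
    dictionary: Sequence[DrugEntry] | None = None,
    grace_days: int = DEFAULT_GRACE_DAYS,
    bedtime_outpatient_only: bool = True,
) -> pd.DataFrame:
    """Episodes for a dataset's analysis prescriptions (bedtime, outpatient)."""
    rx = dataset.prescriptions
    if bedtime_outpatient_only:
        rx = rx[rx["bedtime_flag"] & (rx["setting"] == "outpatient")]
    return build_episodes(rx, dictionary, grace_days)
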