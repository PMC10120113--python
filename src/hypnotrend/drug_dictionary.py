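"""The hypnotic formulary: generic name -> MOA class, duration type, ATC, day cap.

Oral hypnotics marketed for insomnia in Japan during the study window,
classified into five mechanism-of-action (MOA) classes:

* ``BZD`` -- benzodiazepine GABA_A-receptor agonists, subtyped by duration of
  action (long / intermediate / short / ultrashort);
* ``Z_DRUG`` -- non-benzodiazepine GABA_A-receptor agonists (all ultrashort);
* ``MRA`` -- melatonin receptor agonist (ramelteon);
* ``ORA`` -- orexin receptor antagonist (suvorexant; lemborexant was not yet
  marketed and is deliberately absent);
* ``OTHER`` -- barbiturates and miscellaneous sedatives, which carry no
  duration subtype.

Matching is by generic name (case-insensitive), never by ATC code: three
entries (haloxazolam, nimetazepam, rilmazafone) have no ATC code at all.
``max_days_per_rx`` is the Japanese per-prescription day cap; ``None`` means
unrestricted.  Phenobarbital's cap range 30-90 is stored as the permissive
bound 90 so supply QC never raises false positives.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "MOA_CLASSES",
    "DURATION_TYPES",
    "DrugEntry",
    "UnknownDrugError",
    "builtin_dictionary",
    "classify_drug",
    "check_rx_length",
    "classification_index",
    "load_dictionary",
    "dictionary_resource_path",
]

MOA_CLASSES = ("BZD", "Z_DRUG", "MRA", "ORA", "OTHER")
#: Duration-of-action subtypes; only GABA_A-receptor agonists (BZD, Z_DRUG)
#: carry one.
DURATION_TYPES = ("long", "intermediate", "short", "ultrashort")


@dataclass(frozen=True)
class DrugEntry:
    generic_name: str
    moa_class: str
    duration_type: str | None  # None iff moa_class not in {BZD, Z_DRUG}
    atc_code: str | None
    max_days_per_rx: int | None  # None = unrestricted

    def __post_init__(self):
        if self.moa_class not in MOA_CLASSES:
            raise ValueError(f"unknown MOA class {self.moa_class!r}")
        has_duration = self.duration_type is not None
        if has_duration != (self.moa_class in ("BZD", "Z_DRUG")):
            raise ValueError(
                f"{self.generic_name}: duration_type is defined exactly for BZD/Z_DRUG entries"
            )
        if has_duration and self.duration_type not in DURATION_TYPES:
            raise ValueError(f"unknown duration type {self.duration_type!r}")


class UnknownDrugError(KeyError):
    """A generic name not present in the formulary."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"unknown drug generic name: {name!r}")


_BUILTIN: tuple[DrugEntry, ...] = (
    # Benzodiazepines
    DrugEntry("Flurazepam", "BZD", "long", "N05CD01", 30),
    DrugEntry("Quazepam", "BZD", "long", "N05CD10", 30),
    DrugEntry("Haloxazolam", "BZD", "long", None, 30),
    DrugEntry("Nitrazepam", "BZD", "intermediate", "N05CD02", 90),
    DrugEntry("Flunitrazepam", "BZD", "intermediate", "N05CD03", 30),
    DrugEntry("Estazolam", "BZD", "intermediate", "N05CD04", 30),
    DrugEntry("Nimetazepam", "BZD", "intermediate", None, 30),
    DrugEntry("Lormetazepam", "BZD", "short", "N05CD06", 30),
    DrugEntry("Brotizolam", "BZD", "short", "N05CD09", 30),
    DrugEntry("Etizolam", "BZD", "short", "N05BA19", 30),
    DrugEntry("Rilmazafone hydrochloride", "BZD", "short", None, None),
    DrugEntry("Triazolam", "BZD", "ultrashort", "N05CD05", 30),
    # Non-benzodiazepine hypnotics (z-drugs)
    DrugEntry("Zopiclone", "Z_DRUG", "ultrashort", "N05CF01", 30),
    DrugEntry("Zolpidem tartrate", "Z_DRUG", "ultrashort", "N05CF02", 30),
    DrugEntry("Eszopiclone", "Z_DRUG", "ultrashort", "N05CF04", None),
    # Melatonin receptor agonist
    DrugEntry("Ramelteon", "MRA", None, "N05CH02", None),
    # Orexin receptor antagonist
    DrugEntry("Suvorexant", "ORA", None, "N05CM19", None),
    # Others
    DrugEntry("Phenobarbital", "OTHER", None, "N03AA02", 90),
    DrugEntry("Pentobarbital calcium", "OTHER", None, "N05CA01", 14),
    DrugEntry("Amobarbital", "OTHER", None, "N05CA02", 14),
    DrugEntry("Barbital", "OTHER", None, "N05CA04", 14),
    DrugEntry("Chloral hydrate", "OTHER", None, "N05CC01", None),
    DrugEntry("Bromovalerylurea", "OTHER", None, "N05CM03", None),
    DrugEntry("Triclofos sodium", "OTHER", None, "N05CM07", None),
)


def builtin_dictionary() -> tuple[DrugEntry, ...]:
    """The 24-drug built-in formulary (immutable)."""
    return _BUILTIN


def classification_index(dictionary: Sequence[DrugEntry] | None = None) -> dict[str, DrugEntry]:
    """Lower-cased generic-name -> entry lookup table."""
    entries = _BUILTIN if dictionary is None else tuple(dictionary)
    index = {}
    for entry in entries:
        key = entry.generic_name.lower()
        if key in index:
            raise ValueError(f"duplicate generic name in dictionary: {entry.generic_name!r}")
        index[key] = entry
    if not index:
        raise ValueError("empty drug dictionary")
    return index


def classify_drug(name: str, dictionary: Sequence[DrugEntry] | None = None) -> DrugEntry:
    """Resolve a generic name (case-insensitive exact match) to its entry.

    Raises :class:`UnknownDrugError` for any name outside the formulary --
    including lemborexant, which was not marketed during the study window.
    """
    try:
        return classification_index(dictionary)[name.strip().lower()]
    except KeyError:
        raise UnknownDrugError(name) from None


def check_rx_length(days_supplied: int, entry: DrugEntry) -> bool:
    """Advisory QC: True iff the supply exceeds the per-prescription day cap.

    Never raised for unrestricted drugs; the flag never excludes a claim.
    """
    return entry.max_days_per_rx is not None and days_supplied > entry.max_days_per_rx


_RESOURCE = "hypnotic_formulary.csv"


def dictionary_resource_path() -> Path:
    """Path of the packaged formulary CSV (mirrors the built-in entries)."""
    return Path(str(resources.files("hypnotrend").joinpath("data", _RESOURCE)))


def load_dictionary(path: str | Path | None = None) -> tuple[DrugEntry, ...]:
    """Load a formulary from a delimited file (columns as the packaged CSV).

    ``duration_type`` and ``atc_code`` may be empty; an empty
    ``max_days_per_rx`` means unrestricted.  User-supplied files may extend or
    override the built-in formulary via the pipeline config.
    """
    path = dictionary_resource_path() if path is None else Path(path)
    entries: list[DrugEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        for row in csv.DictReader(fh, delimiter=sep):
            entries.append(
                DrugEntry(
                    generic_name=row["generic_name"].strip(),
                    moa_class=row["moa_class"].strip(),
                    duration_type=row["duration_type"].strip() or None,
                    atc_code=row["atc_code"].strip() or None,
                    max_days_per_rx=int(row["max_days_per_rx"]) if row["max_days_per_rx"].strip() else None,
                )
            )
    return tuple(entries)


def write_dictionary(entries: Iterable[DrugEntry], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t" if path.suffix.lower() == ".tsv" else ",")
        writer.writerow(["generic_name", "moa_class", "duration_type", "atc_code", "max_days_per_rx"])
        for e in entries:
            writer.writerow(
                [
                    e.generic_name,
                    e.moa_class,
                    e.duration_type or "",
                    e.atc_code or "",
                    "" if e.max_days_per_rx is None else e.max_days_per_rx,
                ]
            )
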