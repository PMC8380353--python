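"""Registry data model and CSV input/output.

A joint registry records one row per primary total hip replacement (THR):
the patient's gender, the implanted construct (femoral stem brand,
acetabular cup brand and bearing couple), the date of the primary
operation, and — when they occurred before the data extraction date — the
date of the first revision and the date of death.

The construct is the unit of analysis: the same stem articulating with a
different cup, or through a different bearing couple, is a different
construct.  Follow-up is measured from the primary operation; failure is
the first revision, and patients are censored at death or at the registry
extraction date, whichever comes first.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

log = logging.getLogger(__name__)

#: Days per year used to convert day-resolution follow-up into years.
DAYS_PER_YEAR = 365.25

REQUIRED_COLUMNS = (
    "procedure_id",
    "gender",
    "stem_brand",
    "cup_brand",
    "bearing",
    "primary_date",
    "revision_date",
    "death_date",
)


class HipbenchError(Exception):
    """Base class for all errors raised by this package."""


class RegistryError(HipbenchError, ValueError):
    """Malformed registry data: bad columns, dates, or invariant violations."""


class Bearing(str, Enum):
    """Bearing couple of the articulation.

    MP = metal-on-polyethylene, CP = ceramic-on-polyethylene,
    CC = ceramic-on-ceramic, MoM = metal-on-metal.  Analyses include MP,
    CP and CC; metal-on-metal and other hard-on-hard bearings are excluded.
    """

    MP = "MP"
    CP = "CP"
    CC = "CC"
    MoM = "MoM"
    other = "other"


#: Bearing couples retained by :func:`filter_bearings`.
INCLUDED_BEARINGS = frozenset({Bearing.MP, Bearing.CP, Bearing.CC})


class Gender(str, Enum):
    female = "female"
    male = "male"


@dataclass(frozen=True, order=True)
class Construct:
    """A stem brand / cup brand / bearing couple combination."""

    stem_brand: str
    cup_brand: str
    bearing: Bearing

    @property
    def label(self) -> str:
        """Display label, e.g. ``"ExeterV40/Trident MP"``."""
        return f"{self.stem_brand}/{self.cup_brand} {self.bearing.value}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass
class ProcedureRecord:
    """One primary THR: the registry row.

    ``revision_date`` and ``death_date`` are ``None`` when the event had
    not occurred (or was not linked) by the extraction date.  ``gender``
    may be ``None``; such records contribute to the all-procedures
    analysis and are dropped from gender strata.
    """

    procedure_id: str
    gender: Optional[Gender]
    stem_brand: str
    cup_brand: str
    bearing: Bearing
    primary_date: date
    revision_date: Optional[date] = None
    death_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.revision_date is not None and self.revision_date < self.primary_date:
            raise RegistryError(
                f"procedure {self.procedure_id!r}: revision_date "
                f"{self.revision_date} precedes primary_date {self.primary_date}"
            )
        if self.death_date is not None and self.death_date < self.primary_date:
            raise RegistryError(
                f"procedure {self.procedure_id!r}: death_date "
                f"{self.death_date} precedes primary_date {self.primary_date}"
            )

    @property
    def construct(self) -> Construct:
        return Construct(self.stem_brand, self.cup_brand, self.bearing)


@dataclass(frozen=True)
class TimeToEvent:
    """Follow-up in years from the primary operation.

    ``event`` is true when the first revision was observed; otherwise the
    record is censored (death or administrative censoring at extraction).
    """

    time_years: float
    event: bool


def _parse_date(value: str, *, row: int, column: str) -> Optional[date]:
    value = value.strip()
    if not value:
        return None
    try:
        return date.fromisoformat(value)
    except ValueError as exc:
        raise RegistryError(
            f"row {row}: unparseable date {value!r} in column {column!r}"
        ) from exc


def read_registry(path: Union[str, Path]) -> list[ProcedureRecord]:
    """Read a registry CSV into a list of :class:`ProcedureRecord`.

    The dialect is UTF-8, comma-separated, with a mandatory header row and
    ISO-8601 dates; blank cells mean "absent".  Row order is preserved.

    Raises
    ------
    RegistryError
        If a mandatory column is missing, a date fails to parse (the error
        names the 1-based data row), or a record violates the date
        ordering invariants.  Unknown bearing codes are *not* an error:
        the record is kept with ``bearing=other`` and a warning is logged.
    """
    path = Path(path)
    records: list[ProcedureRecord] = []
    n_unknown_bearing = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RegistryError(f"{path}: empty file, header row required")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise RegistryError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        for i, row in enumerate(reader, start=1):
            try:
                bearing = Bearing(row["bearing"].strip())
            except ValueError:
                bearing = Bearing.other
                n_unknown_bearing += 1
                log.warning("row %d: unknown bearing code %r kept as 'other'", i, row["bearing"])
            gender_raw = (row["gender"] or "").strip()
            if gender_raw:
                try:
                    gender: Optional[Gender] = Gender(gender_raw.lower())
                except ValueError as exc:
                    raise RegistryError(f"row {i}: unknown gender code {gender_raw!r}") from exc
            else:
                gender = None
            try:
                record = ProcedureRecord(
                    procedure_id=row["procedure_id"],
                    gender=gender,
                    stem_brand=row["stem_brand"].strip(),
                    cup_brand=row["cup_brand"].strip(),
                    bearing=bearing,
                    primary_date=_require_date(row["primary_date"], row=i, column="primary_date"),
                    revision_date=_parse_date(row["revision_date"], row=i, column="revision_date"),
                    death_date=_parse_date(row["death_date"], row=i, column="death_date"),
                )
            except RegistryError as exc:
                raise RegistryError(f"row {i}: {exc}") from None
            records.append(record)
    if n_unknown_bearing:
        log.warning("%d record(s) had unknown bearing codes", n_unknown_bearing)
    return records


def _require_date(value: str, *, row: int, column: str) -> date:
    parsed = _parse_date(value, row=row, column=column)
    if parsed is None:
        raise RegistryError(f"row {row}: column {column!r} is mandatory but blank")
    return parsed


def write_registry(records: Iterable[ProcedureRecord], path: Union[str, Path]) -> None:
    """Write records to the registry CSV dialect (inverse of :func:`read_registry`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.procedure_id,
                    r.gender.value if r.gender is not None else "",
                    r.stem_brand,
                    r.cup_brand,
                    r.bearing.value,
                    r.primary_date.isoformat(),
                    r.revision_date.isoformat() if r.revision_date else "",
                    r.death_date.isoformat() if r.death_date else "",
                ]
            )


def filter_bearings(
    records: Sequence[ProcedureRecord],
    included: frozenset[Bearing] = INCLUDED_BEARINGS,
) -> list[ProcedureRecord]:
    """Keep records whose bearing couple is in ``included`` (default MP/CP/CC).

    Metal-on-metal and other hard-on-hard bearings are dropped.  Relative
    order is preserved; the number excluded is logged.  Idempotent.
    """
    kept = [r for r in records if r.bearing in included]
    n_excluded = len(records) - len(kept)
    if n_excluded:
        log.info("filter_bearings: excluded %d record(s) outside %s",
                 n_excluded, sorted(b.value for b in included))
    return kept


def derive_time_to_event(record: ProcedureRecord, extraction_date: date) -> TimeToEvent:
    """Derive follow-up time and revision status for one procedure.

    The observation window closes at ``min(death_date, extraction_date)``.
    A revision on or before that close is the event; otherwise the record
    is censored at the close.  Times are day differences divided by 365.25.

    A revision recorded *after* death (a data error) is treated as
    censoring at death, with a warning.
    """
    if extraction_date < record.primary_date:
        raise RegistryError(
            f"procedure {record.procedure_id!r}: primary_date {record.primary_date} "
            f"is after the extraction date {extraction_date}"
        )
    close = extraction_date
    if record.death_date is not None and record.death_date < close:
        close = record.death_date
    if record.revision_date is not None and record.revision_date <= close:
        days = (record.revision_date - record.primary_date).days
        return TimeToEvent(time_years=days / DAYS_PER_YEAR, event=True)
    if (
        record.revision_date is not None
        and record.death_date is not None
        and record.revision_date > record.death_date
    ):
        log.warning(
            "procedure %r: revision_date after death_date; censored at death",
            record.procedure_id,
        )
    days = (close - record.primary_date).days
    return TimeToEvent(time_years=days / DAYS_PER_YEAR, event=False)
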