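"""Domain records for trial-to-administrative record linkage.

Two tables are linked: a clinical-trial roster (one row per enrolled
patient) and a hospital-admissions table (one row per admission, with an
encrypted patient identifier). Matching never sees names or addresses;
it uses only the indirect identifiers carried on :class:`MatchKey`:
treatment site, gender, birth year, birth month, and the year and month
of the patient's "event" — enrollment on the trial side (replaced by the
transfer date for patients who transferred into a participating
hospital), index admission on the administrative side.

Tables may come in two dialects: with full birth dates, or with birth
year/month only (the indirect-only dialect, which cannot support the
direct date-of-birth merge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Optional

from .errors import DataError

__all__ = [
    "TrialRecord",
    "AdminAdmission",
    "AdminIndexRecord",
    "MatchKey",
    "effective_event_date",
    "normalize_gender",
    "trial_match_key",
    "admin_match_key",
]

GENDERS = ("M", "F")


def normalize_gender(token: Optional[str]) -> Optional[str]:
    """Normalize a gender token case-insensitively to ``"M"``/``"F"``.

    Empty/None is returned as None (missing); any other token raises
    :class:`DataError`.
    """
    if token is None:
        return None
    tok = token.strip()
    if tok == "":
        return None
    up = tok.upper()
    if up in ("M", "MALE"):
        return "M"
    if up in ("F", "FEMALE"):
        return "F"
    raise DataError(f"unknown gender token {token!r} (expected M or F)")


def _check_birth_fields(obj) -> None:
    if obj.birth_date is not None:
        if obj.birth_year is not None and obj.birth_year != obj.birth_date.year:
            raise DataError(
                f"{obj!r}: birth_year {obj.birth_year} contradicts "
                f"birth_date {obj.birth_date}"
            )
        if obj.birth_month is not None and obj.birth_month != obj.birth_date.month:
            raise DataError(
                f"{obj!r}: birth_month {obj.birth_month} contradicts "
                f"birth_date {obj.birth_date}"
            )
        object.__setattr__(obj, "birth_year", obj.birth_date.year)
        object.__setattr__(obj, "birth_month", obj.birth_date.month)
    if obj.birth_month is not None and not 1 <= obj.birth_month <= 12:
        raise DataError(f"{obj!r}: birth_month {obj.birth_month} not in 1..12")
    if obj.gender is not None and obj.gender not in GENDERS:
        raise DataError(f"{obj!r}: gender must be 'M' or 'F', got {obj.gender!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One enrolled trial patient.

    ``birth_date`` may be omitted in the indirect-only dialect, in which
    case ``birth_year``/``birth_month`` must be supplied directly. When
    ``birth_date`` is present the year/month fields are derived from it.
    """

    trial_id: str
    site_id: str
    gender: Optional[str]
    enrollment_date: date
    birth_date: Optional[date] = None
    birth_year: Optional[int] = None
    birth_month: Optional[int] = None
    transfer_date: Optional[date] = None
    race: Optional[str] = None
    insurance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.enrollment_date is None:
            raise DataError(f"trial record {self.trial_id!r}: missing enrollment_date")
        _check_birth_fields(self)
        if self.birth_date is not None and self.enrollment_date < self.birth_date:
            raise DataError(
                f"trial record {self.trial_id!r}: enrollment_date "
                f"{self.enrollment_date} precedes birth_date {self.birth_date}"
            )
        if (
            self.birth_date is None
            and self.birth_year is not None
            and self.birth_month is not None
        ):
            if (self.enrollment_date.year, self.enrollment_date.month) < (
                self.birth_year,
                self.birth_month,
            ):
                raise DataError(
                    f"trial record {self.trial_id!r}: enrollment precedes "
                    f"birth year/month"
                )
        if self.transfer_date is not None and self.transfer_date < self.enrollment_date:
            raise DataError(
                f"trial record {self.trial_id!r}: transfer_date "
                f"{self.transfer_date} precedes enrollment_date {self.enrollment_date}"
            )


@dataclass(frozen=True)
class AdminAdmission:
    """One administrative admission of one (encrypted) patient."""

    admin_id: str
    site_id: str
    gender: Optional[str]
    admission_date: date
    icd9_codes: tuple[str, ...] = ()
    birth_date: Optional[date] = None
    birth_year: Optional[int] = None
    birth_month: Optional[int] = None

    def __post_init__(self) -> None:
        if self.admission_date is None:
            raise DataError(f"admission {self.admin_id!r}: missing admission_date")
        _check_birth_fields(self)
        if self.birth_date is not None and self.admission_date < self.birth_date:
            raise DataError(
                f"admission {self.admin_id!r}: admission_date "
                f"{self.admission_date} precedes birth_date {self.birth_date}"
            )
        if not isinstance(self.icd9_codes, tuple):
            object.__setattr__(self, "icd9_codes", tuple(self.icd9_codes))


@dataclass(frozen=True)
class AdminIndexRecord:
    """One administrative patient, reduced to the index (earliest
    qualifying) admission. At most one per (site_id, admin_id)."""

    admin_id: str
    site_id: str
    gender: Optional[str]
    admission_date: date
    birth_date: Optional[date] = None
    birth_year: Optional[int] = None
    birth_month: Optional[int] = None

    def __post_init__(self) -> None:
        _check_birth_fields(self)


@dataclass(frozen=True)
class MatchKey:
    """The six indirect identifiers compared by the stepwise algorithm.

    ``event_year``/``event_month`` refer to the effective enrollment date
    on the trial side and the index admission date on the administrative
    side.
    """

    site_id: str
    gender: str
    birth_year: int
    birth_month: int
    event_year: int
    event_month: int

    def __post_init__(self) -> None:
        if not 1 <= self.birth_month <= 12:
            raise DataError(f"MatchKey birth_month {self.birth_month} not in 1..12")
        if not 1 <= self.event_month <= 12:
            raise DataError(f"MatchKey event_month {self.event_month} not in 1..12")


def effective_event_date(record: TrialRecord) -> date:
    """Event date used for matching: the transfer date when the patient
    transferred into a participating hospital, else the enrollment date.
    """
    if record.enrollment_date is None:  # guards hand-built records
        raise DataError(f"trial record {record.trial_id!r}: missing enrollment_date")
    if record.transfer_date is not None:
        return record.transfer_date
    return record.enrollment_date


def trial_match_key(record: TrialRecord) -> Optional[MatchKey]:
    """Derive the six-variable key, or None if a required field is missing."""
    if record.gender is None or record.birth_year is None or record.birth_month is None:
        return None
    event = effective_event_date(record)
    return MatchKey(
        site_id=record.site_id,
        gender=record.gender,
        birth_year=record.birth_year,
        birth_month=record.birth_month,
        event_year=event.year,
        event_month=event.month,
    )


def admin_match_key(record: AdminIndexRecord) -> Optional[MatchKey]:
    """Derive the six-variable key, or None if a required field is missing."""
    if record.gender is None or record.birth_year is None or record.birth_month is None:
        return None
    return MatchKey(
        site_id=record.site_id,
        gender=record.gender,
        birth_year=record.birth_year,
        birth_month=record.birth_month,
        event_year=record.admission_date.year,
        event_month=record.admission_date.month,
    )
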