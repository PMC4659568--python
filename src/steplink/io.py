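"""CSV readers and writers for the trial roster, admissions table,
index records and ground-truth links.

All dates are ISO 8601 (YYYY-MM-DD). Two header dialects are accepted for
the patient tables: the full dialect carries a ``birth_date`` column; the
indirect-only dialect carries ``birth_year`` and ``birth_month`` instead
(and cannot support the direct date-of-birth merge). ICD-9 codes are
semicolon-delimited within their cell.
"""

from __future__ import annotations

import csv
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import DataError
from .records import (
    AdminAdmission,
    AdminIndexRecord,
    TrialRecord,
    normalize_gender,
)

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "read_admin_table",
    "write_admin_table",
    "read_admin_index_table",
    "write_admin_index_table",
    "read_truth_links",
    "write_truth_links",
]

PathLike = Union[str, Path]

TRIAL_COLUMNS = (
    "trial_id",
    "site_id",
    "gender",
    "birth_date",
    "enrollment_date",
    "transfer_date",
    "race",
    "insurance",
)
TRIAL_COLUMNS_INDIRECT = (
    "trial_id",
    "site_id",
    "gender",
    "birth_year",
    "birth_month",
    "enrollment_date",
    "transfer_date",
    "race",
    "insurance",
)
ADMIN_COLUMNS = (
    "admin_id",
    "site_id",
    "gender",
    "birth_date",
    "admission_date",
    "icd9_codes",
)
ADMIN_COLUMNS_INDIRECT = (
    "admin_id",
    "site_id",
    "gender",
    "birth_year",
    "birth_month",
    "admission_date",
    "icd9_codes",
)


def _parse_date(value: str, row: int, column: str) -> Optional[date]:
    value = value.strip()
    if value == "":
        return None
    try:
        return date.fromisoformat(value)
    except ValueError as exc:
        raise DataError(f"row {row}: unparseable date in {column!r}: {value!r}") from exc


def _parse_int(value: str, row: int, column: str) -> Optional[int]:
    value = value.strip()
    if value == "":
        return None
    try:
        return int(value)
    except ValueError as exc:
        raise DataError(f"row {row}: unparseable integer in {column!r}: {value!r}") from exc


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value or None


def _read_rows(path: PathLike, full_cols, indirect_cols):
    """Read a CSV, decide which dialect its header matches, yield rows."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or ())
        if set(header) >= set(full_cols) and "birth_date" in header:
            dialect = "full"
        elif set(header) >= set(indirect_cols):
            dialect = "indirect"
        else:
            raise DataError(
                f"{path}: unrecognized header {list(header)}; expected columns "
                f"{list(full_cols)} or {list(indirect_cols)}"
            )
        rows = list(reader)
    return dialect, rows


def read_trial_table(path: PathLike) -> list[TrialRecord]:
    """Read a trial roster CSV into typed records.

    Raises :class:`DataError` (with the offending row number, header = row 1)
    on unknown gender tokens, unparseable dates or duplicate trial ids.
    """
    dialect, rows = _read_rows(path, TRIAL_COLUMNS, TRIAL_COLUMNS_INDIRECT)
    records: list[TrialRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        trial_id = row["trial_id"].strip()
        if not trial_id:
            raise DataError(f"row {i}: empty trial_id")
        if trial_id in seen:
            raise DataError(f"row {i}: duplicate trial_id {trial_id!r}")
        seen.add(trial_id)
        try:
            gender = normalize_gender(row.get("gender"))
            enrollment = _parse_date(row.get("enrollment_date", ""), i, "enrollment_date")
            if enrollment is None:
                raise DataError(f"row {i}: missing enrollment_date for {trial_id!r}")
            rec = TrialRecord(
                trial_id=trial_id,
                site_id=row["site_id"].strip(),
                gender=gender,
                enrollment_date=enrollment,
                birth_date=(
                    _parse_date(row.get("birth_date", ""), i, "birth_date")
                    if dialect == "full"
                    else None
                ),
                birth_year=(
                    _parse_int(row.get("birth_year", ""), i, "birth_year")
                    if dialect == "indirect"
                    else None
                ),
                birth_month=(
                    _parse_int(row.get("birth_month", ""), i, "birth_month")
                    if dialect == "indirect"
                    else None
                ),
                transfer_date=_parse_date(row.get("transfer_date", ""), i, "transfer_date"),
                race=_opt(row.get("race", "")),
                insurance=_opt(row.get("insurance", "")),
            )
        except DataError as exc:
            raise DataError(f"row {i}: {exc}") if "row" not in str(exc) else exc
        records.append(rec)
    return records


def write_trial_table(records: Sequence[TrialRecord], path: PathLike) -> None:
    indirect = any(r.birth_date is None for r in records)
    cols = TRIAL_COLUMNS_INDIRECT if indirect else TRIAL_COLUMNS
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            row = {
                "trial_id": r.trial_id,
                "site_id": r.site_id,
                "gender": r.gender or "",
                "birth_date": r.birth_date.isoformat() if r.birth_date else "",
                "birth_year": "" if r.birth_year is None else str(r.birth_year),
                "birth_month": "" if r.birth_month is None else str(r.birth_month),
                "enrollment_date": r.enrollment_date.isoformat(),
                "transfer_date": r.transfer_date.isoformat() if r.transfer_date else "",
                "race": r.race or "",
                "insurance": r.insurance or "",
            }
            writer.writerow([row[c] for c in cols])


def read_admin_table(path: PathLike) -> list[AdminAdmission]:
    """Read an admissions CSV; ICD-9 codes are split on semicolons."""
    dialect, rows = _read_rows(path, ADMIN_COLUMNS, ADMIN_COLUMNS_INDIRECT)
    records: list[AdminAdmission] = []
    for i, row in enumerate(rows, start=2):
        admission = _parse_date(row.get("admission_date", ""), i, "admission_date")
        if admission is None:
            raise DataError(f"row {i}: missing admission_date")
        codes = tuple(
            c.strip() for c in row.get("icd9_codes", "").split(";") if c.strip()
        )
        try:
            rec = AdminAdmission(
                admin_id=row["admin_id"].strip(),
                site_id=row["site_id"].strip(),
                gender=normalize_gender(row.get("gender")),
                admission_date=admission,
                icd9_codes=codes,
                birth_date=(
                    _parse_date(row.get("birth_date", ""), i, "birth_date")
                    if dialect == "full"
                    else None
                ),
                birth_year=(
                    _parse_int(row.get("birth_year", ""), i, "birth_year")
                    if dialect == "indirect"
                    else None
                ),
                birth_month=(
                    _parse_int(row.get("birth_month", ""), i, "birth_month")
                    if dialect == "indirect"
                    else None
                ),
            )
        except DataError as exc:
            raise DataError(f"row {i}: {exc}") if "row" not in str(exc) else exc
        records.append(rec)
    return records


def write_admin_table(records: Sequence[AdminAdmission], path: PathLike) -> None:
    indirect = any(r.birth_date is None for r in records)
    cols = ADMIN_COLUMNS_INDIRECT if indirect else ADMIN_COLUMNS
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            row = {
                "admin_id": r.admin_id,
                "site_id": r.site_id,
                "gender": r.gender or "",
                "birth_date": r.birth_date.isoformat() if r.birth_date else "",
                "birth_year": "" if r.birth_year is None else str(r.birth_year),
                "birth_month": "" if r.birth_month is None else str(r.birth_month),
                "admission_date": r.admission_date.isoformat(),
                "icd9_codes": ";".join(r.icd9_codes),
            }
            writer.writerow([row[c] for c in cols])


INDEX_COLUMNS = ("admin_id", "site_id", "gender", "birth_date", "admission_date")
INDEX_COLUMNS_INDIRECT = (
    "admin_id",
    "site_id",
    "gender",
    "birth_year",
    "birth_month",
    "admission_date",
)


def read_admin_index_table(path: PathLike) -> list[AdminIndexRecord]:
    dialect, rows = _read_rows(path, INDEX_COLUMNS, INDEX_COLUMNS_INDIRECT)
    records = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=2):
        admission = _parse_date(row.get("admission_date", ""), i, "admission_date")
        if admission is None:
            raise DataError(f"row {i}: missing admission_date")
        key = (row["site_id"].strip(), row["admin_id"].strip())
        if key in seen:
            raise DataError(f"row {i}: duplicate index record for {key}")
        seen.add(key)
        records.append(
            AdminIndexRecord(
                admin_id=key[1],
                site_id=key[0],
                gender=normalize_gender(row.get("gender")),
                admission_date=admission,
                birth_date=(
                    _parse_date(row.get("birth_date", ""), i, "birth_date")
                    if dialect == "full"
                    else None
                ),
                birth_year=(
                    _parse_int(row.get("birth_year", ""), i, "birth_year")
                    if dialect == "indirect"
                    else None
                ),
                birth_month=(
                    _parse_int(row.get("birth_month", ""), i, "birth_month")
                    if dialect == "indirect"
                    else None
                ),
            )
        )
    return records


def write_admin_index_table(records: Sequence[AdminIndexRecord], path: PathLike) -> None:
    indirect = any(r.birth_date is None for r in records)
    cols = INDEX_COLUMNS_INDIRECT if indirect else INDEX_COLUMNS
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            row = {
                "admin_id": r.admin_id,
                "site_id": r.site_id,
                "gender": r.gender or "",
                "birth_date": r.birth_date.isoformat() if r.birth_date else "",
                "birth_year": "" if r.birth_year is None else str(r.birth_year),
                "birth_month": "" if r.birth_month is None else str(r.birth_month),
                "admission_date": r.admission_date.isoformat(),
            }
            writer.writerow([row[c] for c in cols])


def read_truth_links(path: PathLike) -> dict[str, Optional[str]]:
    """Read ground-truth links (``trial_id,admin_id``; empty admin_id means
    the patient is absent from the administrative source)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if set(reader.fieldnames or ()) < {"trial_id", "admin_id"}:
            raise DataError(f"{path}: truth file needs columns trial_id,admin_id")
        links: dict[str, Optional[str]] = {}
        for i, row in enumerate(reader, start=2):
            tid = row["trial_id"].strip()
            if tid in links:
                raise DataError(f"row {i}: duplicate trial_id {tid!r} in truth file")
            links[tid] = _opt(row["admin_id"])
    return links


def write_truth_links(links: dict[str, Optional[str]], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(("trial_id", "admin_id"))
        for tid in links:
            writer.writerow((tid, links[tid] or ""))
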