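"""Cohort construction applied to the admissions table before matching.

Admissions qualify when they fall inside the trial's open window and carry
at least one ICD-9-CM code for acute myeloid leukemia or unspecified
leukemia (three-digit roots 205, 206, 207, 208). Qualifying admissions are
then collapsed to one index record per (site, encrypted patient id),
carrying the earliest qualifying admission date, so that matching is
patient-level and "multiple matches" means multiple distinct patients.
"""

from __future__ import annotations

import logging
import re
from datetime import date
from typing import Iterable, Optional, Sequence

from .errors import DataError
from .records import AdminAdmission, AdminIndexRecord

__all__ = [
    "AML_ICD9_ROOTS",
    "icd9_root",
    "is_aml_code",
    "filter_aml_cohort",
    "derive_index_records",
]

logger = logging.getLogger(__name__)

#: three-digit ICD-9 roots for AML or unspecified leukemia
AML_ICD9_ROOTS = frozenset({"205", "206", "207", "208"})

_ICD9_RE = re.compile(r"^(\d{3})(?:\.\d{1,2})?$")


def icd9_root(code: str) -> Optional[str]:
    """Three-digit root of an ICD-9-CM diagnosis code, or None if the
    code string is malformed (malformed codes are logged and treated as
    non-qualifying)."""
    m = _ICD9_RE.match(code.strip())
    if m is None:
        logger.warning("malformed ICD-9 code %r treated as non-qualifying", code)
        return None
    return m.group(1)


def is_aml_code(code: str) -> bool:
    return icd9_root(code) in AML_ICD9_ROOTS


def filter_aml_cohort(
    admissions: Iterable[AdminAdmission],
    window: tuple[date, date],
) -> list[AdminAdmission]:
    """Keep admissions inside the closed ``window`` that carry at least one
    qualifying leukemia code."""
    start, end = window
    if start > end:
        raise DataError(f"cohort window start {start} is after end {end}")
    kept = []
    for adm in admissions:
        if not start <= adm.admission_date <= end:
            continue
        if any(is_aml_code(code) for code in adm.icd9_codes):
            kept.append(adm)
    return kept


def _index_sort_key(adm: AdminAdmission):
    # deterministic under input permutation: earliest date, then stable
    # tie-break on the remaining attributes
    return (
        adm.admission_date,
        adm.birth_date or date.max,
        adm.birth_year or 0,
        adm.birth_month or 0,
        adm.gender or "",
        getattr(adm, "icd9_codes", ()),
    )


def derive_index_records(
    admissions: Sequence[AdminAdmission],
) -> list[AdminIndexRecord]:
    """Collapse admissions to one index record per (site_id, admin_id),
    dated at the earliest admission.

    Conflicting demographics across a patient's admissions are resolved in
    favour of the earliest admission, with a logged warning.
    """
    groups: dict[tuple[str, str], list[AdminAdmission]] = {}
    for adm in admissions:
        groups.setdefault((adm.site_id, adm.admin_id), []).append(adm)

    out = []
    for (site_id, admin_id) in sorted(groups):
        adms = sorted(groups[(site_id, admin_id)], key=_index_sort_key)
        first = adms[0]
        for other in adms[1:]:
            if (
                other.gender != first.gender
                or other.birth_year != first.birth_year
                or other.birth_month != first.birth_month
                or other.birth_date != first.birth_date
            ):
                logger.warning(
                    "patient (%s, %s): conflicting demographics across "
                    "admissions; using the earliest admission's values",
                    site_id,
                    admin_id,
                )
                break
        out.append(
            AdminIndexRecord(
                admin_id=admin_id,
                site_id=site_id,
                gender=first.gender,
                admission_date=first.admission_date,
                birth_date=first.birth_date,
                birth_year=first.birth_year,
                birth_month=first.birth_month,
            )
        )
    return out
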