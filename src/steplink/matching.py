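"""Deterministic stepwise record linkage on indirect identifiers.

The model object is :class:`StepwiseLinkage`: built from a trial roster and
a pool of administrative index records plus a relaxation schedule
(:data:`steplink.steps.DEFAULT_STEPS` by default). ``fit()`` runs the
cascade and returns :class:`LinkageResults`.

Within one step, every still-unmatched trial record is compared against
every still-unmatched administrative patient. A trial record is classified

* ``NO_MATCH`` — zero candidates agree with it under the step's rule;
* ``MULTIPLE_ADMIN`` — two or more administrative candidates agree
  (forward ambiguity, "matched with multiple admin records");
* ``MULTIPLE_TRIAL`` — it has exactly one candidate, but at least one
  other available trial record has that same sole candidate (reverse
  contention, "multiple trial records for one admin patient");
* ``UNIQUE`` — exactly one candidate, claimed by no other trial record.

Uniquely matched trial records and their assigned administrative patients
are removed from all subsequent steps (carry-forward), which makes the
final assignment one-to-one by construction.

:class:`DirectLinkage` is the comparator: a single-pass exact merge on
(full date of birth, site, gender). It refuses to run on indirect-only
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigError, DataError, DialectError
from .records import (
    AdminIndexRecord,
    MatchKey,
    TrialRecord,
    admin_match_key,
    trial_match_key,
)
from .steps import DEFAULT_STEPS, MatchStep, MonthMode, YearMode

__all__ = [
    "MatchClassification",
    "StepResult",
    "LinkageResults",
    "StepwiseLinkage",
    "DirectOutcome",
    "DirectResults",
    "DirectLinkage",
    "keys_agree",
    "candidates",
    "classify_step",
    "run_stepwise",
    "run_direct",
]

logger = logging.getLogger(__name__)


class MatchClassification(str, Enum):
    UNIQUE = "UNIQUE"
    NO_MATCH = "NO_MATCH"
    MULTIPLE_ADMIN = "MULTIPLE_ADMIN"
    MULTIPLE_TRIAL = "MULTIPLE_TRIAL"


def keys_agree(trial_key: MatchKey, admin_key: MatchKey, step: MatchStep) -> bool:
    """Do two six-variable keys agree under one step's rule?

    Site, gender, birth year and birth month are always compared exactly;
    the step decides how the event year/month are treated. The comparison
    is symmetric in its two arguments.
    """
    if (
        trial_key.site_id != admin_key.site_id
        or trial_key.gender != admin_key.gender
        or trial_key.birth_year != admin_key.birth_year
        or trial_key.birth_month != admin_key.birth_month
    ):
        return False
    if step.year_mode is YearMode.EXACT:
        if trial_key.event_year != admin_key.event_year:
            return False
    elif step.year_mode is YearMode.TOLERANCE:
        if abs(trial_key.event_year - admin_key.event_year) > step.year_tolerance:
            return False
    if step.month_mode is MonthMode.EXACT:
        if trial_key.event_month != admin_key.event_month:
            return False
    return True


def candidates(
    record: TrialRecord,
    pool: Iterable[AdminIndexRecord],
    step: MatchStep,
) -> set[AdminIndexRecord]:
    """Administrative patients agreeing with ``record`` under ``step``.

    A record missing any always-required field yields the empty set (it
    will be classified NO_MATCH, with a logged warning at classification
    time).
    """
    tkey = trial_match_key(record)
    if tkey is None:
        return set()
    out = set()
    for admin in pool:
        akey = admin_match_key(admin)
        if akey is not None and keys_agree(tkey, akey, step):
            out.add(admin)
    return out


@dataclass(frozen=True)
class StepResult:
    """Classification counts and unique assignments for one step.

    Invariant: ``n_available == n_unique + n_no_match + n_multiple_admin +
    n_multiple_trial``.
    """

    step_number: int
    n_available: int
    n_unique: int
    n_no_match: int
    n_multiple_admin: int
    n_multiple_trial: int
    assignments: dict[str, str]  # trial_id -> admin_id, this step's uniques
    classifications: dict[str, MatchClassification]
    candidate_ids: dict[str, frozenset[str]]  # trial_id -> admin_id set


def classify_step(
    available: Sequence[TrialRecord],
    pool: Sequence[AdminIndexRecord],
    step: MatchStep,
) -> StepResult:
    """Classify every available trial record against ``pool`` under one step."""
    sole: dict[str, list[str]] = {}  # admin_id -> trial_ids whose only candidate it is
    cand_ids: dict[str, frozenset[str]] = {}
    classes: dict[str, MatchClassification] = {}

    admin_keys = [(a, admin_match_key(a)) for a in pool]
    for rec in available:
        tkey = trial_match_key(rec)
        if tkey is None:
            logger.warning(
                "trial record %r missing a matching field; classified NO_MATCH "
                "at step %d",
                rec.trial_id,
                step.step_number,
            )
            cand_ids[rec.trial_id] = frozenset()
            classes[rec.trial_id] = MatchClassification.NO_MATCH
            continue
        cands = frozenset(
            a.admin_id for a, akey in admin_keys if akey is not None and keys_agree(tkey, akey, step)
        )
        cand_ids[rec.trial_id] = cands
        if len(cands) == 0:
            classes[rec.trial_id] = MatchClassification.NO_MATCH
        elif len(cands) >= 2:
            classes[rec.trial_id] = MatchClassification.MULTIPLE_ADMIN
        else:
            sole.setdefault(next(iter(cands)), []).append(rec.trial_id)

    assignments: dict[str, str] = {}
    for admin_id, trial_ids in sole.items():
        if len(trial_ids) == 1:
            classes[trial_ids[0]] = MatchClassification.UNIQUE
            assignments[trial_ids[0]] = admin_id
        else:
            for tid in trial_ids:
                classes[tid] = MatchClassification.MULTIPLE_TRIAL

    counts = {c: 0 for c in MatchClassification}
    for c in classes.values():
        counts[c] += 1
    return StepResult(
        step_number=step.step_number,
        n_available=len(available),
        n_unique=counts[MatchClassification.UNIQUE],
        n_no_match=counts[MatchClassification.NO_MATCH],
        n_multiple_admin=counts[MatchClassification.MULTIPLE_ADMIN],
        n_multiple_trial=counts[MatchClassification.MULTIPLE_TRIAL],
        assignments=assignments,
        classifications=classes,
        candidate_ids=cand_ids,
    )


@dataclass
class LinkageResults:
    """Results of a fitted :class:`StepwiseLinkage`.

    ``trace`` maps each trial id to its per-step
    (step_number, classification, candidate admin ids) history; records
    uniquely matched at an earlier step do not appear in later steps.
    """

    steps: tuple[MatchStep, ...]
    step_results: list[StepResult]
    final_assignments: dict[str, str]
    trace: dict[str, list[tuple[int, MatchClassification, frozenset[str]]]]
    n_trial: int
    matched_step: dict[str, int] = field(default_factory=dict)

    @property
    def n_unique_cumulative(self) -> int:
        return sum(sr.n_unique for sr in self.step_results)

    @property
    def cumulative_unique_by_step(self) -> list[int]:
        out, total = [], 0
        for sr in self.step_results:
            total += sr.n_unique
            out.append(total)
        return out

    def classification_history(self, trial_id: str) -> str:
        """Compact per-step class codes for one record, e.g. ``"N;N;MA;U"``."""
        codes = {
            MatchClassification.UNIQUE: "U",
            MatchClassification.NO_MATCH: "N",
            MatchClassification.MULTIPLE_ADMIN: "MA",
            MatchClassification.MULTIPLE_TRIAL: "MT",
        }
        return ";".join(codes[c] for _, c, _ in self.trace.get(trial_id, []))

    def to_matches_frame(self):
        """Matches table: trial_id, admin_id, matched_step,
        classification_history (one row per trial record)."""
        import pandas as pd

        rows = []
        for tid in sorted(self.trace):
            rows.append(
                {
                    "trial_id": tid,
                    "admin_id": self.final_assignments.get(tid, ""),
                    "matched_step": self.matched_step.get(tid, ""),
                    "classification_history": self.classification_history(tid),
                }
            )
        return pd.DataFrame(rows, columns=["trial_id", "admin_id", "matched_step", "classification_history"])

    def summary(self, concordance=None):
        """Per-step summary table; see :func:`steplink.reporting.step_summary`."""
        from .reporting import step_summary

        return step_summary(self, concordance=concordance)


class StepwiseLinkage:
    """Stepwise indirect-identifier linkage model.

    Parameters
    ----------
    trial : sequence of TrialRecord
    admin : sequence of AdminIndexRecord
        One record per administrative patient (use
        :func:`steplink.cohort.derive_index_records` to collapse raw
        admissions first).
    steps : sequence of MatchStep, optional
        Relaxation schedule; defaults to the four-step schedule.
    """

    def __init__(
        self,
        trial: Sequence[TrialRecord],
        admin: Sequence[AdminIndexRecord],
        steps: Sequence[MatchStep] = DEFAULT_STEPS,
    ) -> None:
        steps = tuple(steps)
        if not steps:
            raise ConfigError("steps must be non-empty")
        numbers = [s.step_number for s in steps]
        if len(set(numbers)) != len(numbers):
            raise ConfigError(f"duplicate step numbers in schedule: {numbers}")
        ids = [r.trial_id for r in trial]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate trial_id(s): {dup}")
        aids = [a.admin_id for a in admin]
        if len(set(aids)) != len(aids):
            dup = sorted({i for i in aids if aids.count(i) > 1})
            raise DataError(
                f"admin pool has duplicate admin_id(s) {dup}; encrypted patient "
                "ids must be unique across the pool (collapse admissions to "
                "index records first)"
            )
        self.trial = tuple(trial)
        self.admin = tuple(admin)
        self.steps = steps

    @classmethod
    def from_csv(cls, trial_path, admin_index_path, steps: Sequence[MatchStep] = DEFAULT_STEPS):
        """Build from a trial roster CSV and an index-record CSV."""
        from .io import read_admin_index_table, read_trial_table

        return cls(read_trial_table(trial_path), read_admin_index_table(admin_index_path), steps)

    def fit(self) -> LinkageResults:
        """Run the cascade with carry-forward and return the results."""
        # sort for determinism under input row permutation
        available = sorted(self.trial, key=lambda r: r.trial_id)
        pool = sorted(self.admin, key=lambda a: (a.site_id, a.admin_id))
        step_results: list[StepResult] = []
        trace: dict[str, list] = {r.trial_id: [] for r in available}
        final: dict[str, str] = {}
        matched_step: dict[str, int] = {}

        for step in self.steps:
            sr = classify_step(available, pool, step)
            step_results.append(sr)
            for rec in available:
                trace[rec.trial_id].append(
                    (step.step_number, sr.classifications[rec.trial_id], sr.candidate_ids[rec.trial_id])
                )
            final.update(sr.assignments)
            for tid in sr.assignments:
                matched_step[tid] = step.step_number
            matched_admin = set(sr.assignments.values())
            available = [r for r in available if r.trial_id not in sr.assignments]
            pool = [a for a in pool if a.admin_id not in matched_admin]

        assert len(set(final.values())) == len(final), "assignments not injective"
        return LinkageResults(
            steps=self.steps,
            step_results=step_results,
            final_assignments=final,
            trace=trace,
            n_trial=len(self.trial),
            matched_step=matched_step,
        )


class DirectOutcome(str, Enum):
    UNIQUE = "UNIQUE"
    NO_MATCH = "NO_MATCH"
    DUPLICATES = "DUPLICATES"
    MULTIPLE_TRIAL = "MULTIPLE_TRIAL"


@dataclass
class DirectResults:
    """Results of the direct (DOB, site, gender) merge.

    ``outcomes`` maps each trial id to ``(kind, admin ids)``: the single
    assigned id for UNIQUE, the duplicate candidate set for DUPLICATES
    (size >= 2), the contested sole candidate for MULTIPLE_TRIAL, and the
    empty set for NO_MATCH.
    """

    outcomes: dict[str, tuple[DirectOutcome, frozenset[str]]]
    assignments: dict[str, str]

    @property
    def counts(self) -> dict[str, int]:
        c = {k.value: 0 for k in DirectOutcome}
        for kind, _ in self.outcomes.values():
            c[kind.value] += 1
        return c

    @property
    def n_unique(self) -> int:
        return len(self.assignments)


class DirectLinkage:
    """Single-pass exact merge on (full birth date, site, gender).

    Raises :class:`DialectError` if either table lacks full birth dates
    (the indirect-only dialect carries only birth year/month, which this
    comparator cannot use).
    """

    def __init__(self, trial: Sequence[TrialRecord], admin: Sequence[AdminIndexRecord]) -> None:
        missing_t = [r.trial_id for r in trial if r.birth_date is None]
        missing_a = [a.admin_id for a in admin if a.birth_date is None]
        if missing_t or missing_a:
            raise DialectError(
                "direct merge needs full birth dates on both sides; "
                f"indirect-only dialect detected (missing on trial: {missing_t[:5]}, "
                f"admin: {missing_a[:5]})"
            )
        self.trial = tuple(trial)
        self.admin = tuple(admin)

    def fit(self) -> DirectResults:
        by_key: dict[tuple, list[str]] = {}
        for a in sorted(self.admin, key=lambda a: (a.site_id, a.admin_id)):
            key = (a.birth_date, a.site_id, a.gender)
            by_key.setdefault(key, []).append(a.admin_id)

        sole: dict[str, list[str]] = {}
        outcomes: dict[str, tuple[DirectOutcome, frozenset[str]]] = {}
        for rec in sorted(self.trial, key=lambda r: r.trial_id):
            cands = by_key.get((rec.birth_date, rec.site_id, rec.gender), [])
            if not cands:
                outcomes[rec.trial_id] = (DirectOutcome.NO_MATCH, frozenset())
            elif len(cands) >= 2:
                outcomes[rec.trial_id] = (DirectOutcome.DUPLICATES, frozenset(cands))
            else:
                sole.setdefault(cands[0], []).append(rec.trial_id)

        assignments: dict[str, str] = {}
        for admin_id, trial_ids in sole.items():
            if len(trial_ids) == 1:
                outcomes[trial_ids[0]] = (DirectOutcome.UNIQUE, frozenset({admin_id}))
                assignments[trial_ids[0]] = admin_id
            else:
                for tid in trial_ids:
                    outcomes[tid] = (DirectOutcome.MULTIPLE_TRIAL, frozenset({admin_id}))
        return DirectResults(outcomes=outcomes, assignments=assignments)


def run_stepwise(
    trial: Sequence[TrialRecord],
    admin: Sequence[AdminIndexRecord],
    steps: Sequence[MatchStep] = DEFAULT_STEPS,
) -> LinkageResults:
    """Functional wrapper: ``StepwiseLinkage(trial, admin, steps).fit()``."""
    return StepwiseLinkage(trial, admin, steps).fit()


def run_direct(
    trial: Sequence[TrialRecord], admin: Sequence[AdminIndexRecord]
) -> DirectResults:
    """Functional wrapper: ``DirectLinkage(trial, admin).fit()``."""
    return DirectLinkage(trial, admin).fit()
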