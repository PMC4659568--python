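"""Concordance of the indirect stepwise merge with the direct merge, and
evaluation against simulation ground truth.

Two criteria are supported. For each unique match ``trial_id -> a`` made
by the stepwise algorithm:

* direct merge also uniquely matched the record to ``a`` — concordant
  under both criteria;
* direct merge uniquely matched it to some ``b != a`` — discordant under
  both;
* direct merge produced duplicate candidates ``S`` — discordant under
  Criterion 1; under Criterion 2, concordant iff ``a`` is in ``S``;
* direct merge found no match, or the record contested an admin patient
  with another trial record — discordant under both.

Criterion 2 therefore relaxes Criterion 1, so C2 concordance >= C1
concordance for every step and cumulatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import DataError
from .matching import DirectOutcome, DirectResults, LinkageResults

__all__ = [
    "StepConcordance",
    "ConcordanceSummary",
    "concordance",
    "EvaluationMetrics",
    "evaluate_against_truth",
]


@dataclass(frozen=True)
class StepConcordance:
    step_number: int
    n_unique: int
    n_concordant: int

    @property
    def proportion(self) -> Optional[float]:
        """Concordant fraction among this step's uniques; None when the
        step produced no unique matches."""
        if self.n_unique == 0:
            return None
        return self.n_concordant / self.n_unique


@dataclass(frozen=True)
class ConcordanceSummary:
    criterion: str  # "C1" or "C2"
    per_step: tuple[StepConcordance, ...]

    @property
    def cumulative_n_unique(self) -> int:
        return sum(s.n_unique for s in self.per_step)

    @property
    def cumulative_n_concordant(self) -> int:
        return sum(s.n_concordant for s in self.per_step)

    @property
    def cumulative_proportion(self) -> Optional[float]:
        if self.cumulative_n_unique == 0:
            return None
        return self.cumulative_n_concordant / self.cumulative_n_unique


def _is_concordant(
    admin_id: str, outcome: tuple[DirectOutcome, frozenset[str]], criterion: str
) -> bool:
    kind, ids = outcome
    if kind is DirectOutcome.UNIQUE:
        return admin_id in ids
    if kind is DirectOutcome.DUPLICATES and criterion == "C2":
        return admin_id in ids
    return False


def concordance(
    indirect: LinkageResults, direct: DirectResults, criterion: str
) -> ConcordanceSummary:
    """Per-step and cumulative concordance of the stepwise uniques with the
    direct merge, under ``criterion`` ("C1" or "C2")."""
    if criterion not in ("C1", "C2"):
        raise ValueError(f"criterion must be 'C1' or 'C2', got {criterion!r}")
    per_step = []
    for sr in indirect.step_results:
        n_conc = 0
        for tid, admin_id in sr.assignments.items():
            if tid not in direct.outcomes:
                raise DataError(
                    f"trial record {tid!r} present in the indirect result but "
                    "absent from the direct merge input; both merges must be "
                    "run on the same trial table"
                )
            if _is_concordant(admin_id, direct.outcomes[tid], criterion):
                n_conc += 1
        per_step.append(
            StepConcordance(
                step_number=sr.step_number,
                n_unique=sr.n_unique,
                n_concordant=n_conc,
            )
        )
    return ConcordanceSummary(criterion=criterion, per_step=tuple(per_step))


@dataclass(frozen=True)
class EvaluationMetrics:
    """Linkage accuracy against simulation ground truth.

    sensitivity
        correct unique matches / truly captured trial records; None (NA)
        when no record was captured.
    ppv
        correct unique matches / all unique matches; 1.0 by convention
        when there are no unique matches.
    """

    n_captured: int
    n_unique: int
    n_correct: int
    n_false_matches: int

    @property
    def sensitivity(self) -> Optional[float]:
        if self.n_captured == 0:
            return None
        return self.n_correct / self.n_captured

    @property
    def ppv(self) -> float:
        if self.n_unique == 0:
            return 1.0
        return self.n_correct / self.n_unique


def evaluate_against_truth(
    result: LinkageResults, truth: dict[str, Optional[str]]
) -> EvaluationMetrics:
    """Score unique assignments against the generative links (``None``
    meaning the patient was never captured in the administrative source)."""
    n_captured = sum(1 for v in truth.values() if v is not None)
    n_correct = 0
    n_false = 0
    for tid, admin_id in result.final_assignments.items():
        if truth.get(tid) == admin_id:
            n_correct += 1
        else:
            n_false += 1
    return EvaluationMetrics(
        n_captured=n_captured,
        n_unique=len(result.final_assignments),
        n_correct=n_correct,
        n_false_matches=n_false,
    )
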