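"""Per-step summary tables and the versioned JSON report.

The summary mirrors the standard presentation of stepwise-linkage results:
one column per step, rows for patients available, unique matches, no
matches, the two multiple-match classes, and the cumulative unique count,
optionally followed by one concordance block per criterion. Within-step
percentages are computed against that step's available count; cumulative
percentages against the initial available count. All percentages are
recomputed from the raw counts at render time and shown to one decimal
place; a zero denominator renders as ``NA``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .concordance import ConcordanceSummary
from .matching import LinkageResults

__all__ = ["StepSummaryTable", "step_summary", "report_dict", "render_report"]

REPORT_SCHEMA_VERSION = "1.0"


def _pct(n: int, denom: int) -> str:
    if denom == 0:
        return "NA"
    return f"{100.0 * n / denom:.1f}%"


def _n_pct(n: int, denom: int) -> str:
    return f"{n} ({_pct(n, denom)})"


@dataclass
class StepSummaryTable:
    """Rendered per-step summary.

    ``frame`` holds the formatted strings (rows in presentation order);
    ``counts`` holds the raw integers the strings were derived from.
    """

    frame: pd.DataFrame
    counts: pd.DataFrame

    def to_text(self) -> str:
        return self.frame.to_string()

    def to_tsv(self) -> str:
        return self.frame.to_csv(sep="\t")


def step_summary(
    result: LinkageResults,
    concordance: Optional[Sequence[ConcordanceSummary]] = None,
) -> StepSummaryTable:
    """Build the per-step summary table for a fitted stepwise linkage."""
    cols = [f"Step {sr.step_number}" for sr in result.step_results]
    n0 = result.step_results[0].n_available if result.step_results else 0

    counts_rows = {
        "available": [sr.n_available for sr in result.step_results],
        "unique": [sr.n_unique for sr in result.step_results],
        "no_match": [sr.n_no_match for sr in result.step_results],
        "multiple_admin": [sr.n_multiple_admin for sr in result.step_results],
        "multiple_trial": [sr.n_multiple_trial for sr in result.step_results],
        "cumulative_unique": result.cumulative_unique_by_step,
    }

    rows: dict[str, list[str]] = {}
    rows["Patients available for match"] = [str(n) for n in counts_rows["available"]]
    for label, key in (
        ("Unique match, n (%)", "unique"),
        ("No match, n (%)", "no_match"),
        ("Multiple admin matches, n (%)", "multiple_admin"),
        ("Multiple trial matches, n (%)", "multiple_trial"),
    ):
        rows[label] = [
            _n_pct(n, avail)
            for n, avail in zip(counts_rows[key], counts_rows["available"])
        ]
    rows["Cumulative unique matches, n (%)"] = [
        _n_pct(n, n0) for n in counts_rows["cumulative_unique"]
    ]

    for summ in concordance or ():
        name = {"C1": "Criterion 1", "C2": "Criterion 2"}.get(summ.criterion, summ.criterion)
        per_step = [
            _n_pct(s.n_concordant, s.n_unique) for s in summ.per_step
        ]
        cum_n, cum_c = 0, 0
        cum_cells = []
        for s in summ.per_step:
            cum_n += s.n_unique
            cum_c += s.n_concordant
            cum_cells.append(_n_pct(cum_c, cum_n))
        rows[f"{name}: concordant among uniques, n (%)"] = per_step
        rows[f"{name}: cumulative concordant, n (%)"] = cum_cells
        counts_rows[f"concordant_{summ.criterion}"] = [s.n_concordant for s in summ.per_step]

    frame = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    counts = pd.DataFrame.from_dict(counts_rows, orient="index", columns=cols)
    return StepSummaryTable(frame=frame, counts=counts)


def report_dict(
    result: LinkageResults,
    concordance: Optional[Sequence[ConcordanceSummary]] = None,
    evaluation=None,
    direct=None,
    seed: Optional[int] = None,
) -> dict:
    """Assemble the versioned JSON-serializable run report."""
    from . import __version__

    steps = [
        {
            "step_number": s.step_number,
            "year_mode": s.year_mode.value,
            "month_mode": s.month_mode.value,
            "year_tolerance": s.year_tolerance,
        }
        for s in result.steps
    ]
    step_blocks = [
        {
            "step_number": sr.step_number,
            "available": sr.n_available,
            "unique": sr.n_unique,
            "no_match": sr.n_no_match,
            "multiple_admin": sr.n_multiple_admin,
            "multiple_trial": sr.n_multiple_trial,
        }
        for sr in result.step_results
    ]
    out = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": seed,
        "steps": steps,
        "stepwise": {
            "n_trial": result.n_trial,
            "per_step": step_blocks,
            "cumulative_unique": result.n_unique_cumulative,
            "cumulative_unique_pct": (
                round(100.0 * result.n_unique_cumulative / result.n_trial, 1)
                if result.n_trial
                else None
            ),
        },
    }
    if direct is not None:
        out["direct"] = {"counts": direct.counts, "n_unique": direct.n_unique}
    if concordance:
        out["concordance"] = {
            summ.criterion: {
                "per_step": [
                    {
                        "step_number": s.step_number,
                        "n_unique": s.n_unique,
                        "n_concordant": s.n_concordant,
                    }
                    for s in summ.per_step
                ],
                "cumulative_n_concordant": summ.cumulative_n_concordant,
                "cumulative_proportion": summ.cumulative_proportion,
            }
            for summ in concordance
        }
    if evaluation is not None:
        out["evaluation"] = {
            "n_captured": evaluation.n_captured,
            "n_unique": evaluation.n_unique,
            "n_correct": evaluation.n_correct,
            "n_false_matches": evaluation.n_false_matches,
            "sensitivity": evaluation.sensitivity,
            "ppv": evaluation.ppv,
        }
    return out


def render_report(report: dict) -> str:
    """Re-render the aligned-text summary table from a stored JSON report."""
    per_step = report["stepwise"]["per_step"]
    cols = [f"Step {b['step_number']}" for b in per_step]
    n0 = per_step[0]["available"] if per_step else 0
    rows = {"Patients available for match": [str(b["available"]) for b in per_step]}
    for label, key in (
        ("Unique match, n (%)", "unique"),
        ("No match, n (%)", "no_match"),
        ("Multiple admin matches, n (%)", "multiple_admin"),
        ("Multiple trial matches, n (%)", "multiple_trial"),
    ):
        rows[label] = [_n_pct(b[key], b["available"]) for b in per_step]
    cum = 0
    cells = []
    for b in per_step:
        cum += b["unique"]
        cells.append(_n_pct(cum, n0))
    rows["Cumulative unique matches, n (%)"] = cells
    for crit, block in (report.get("concordance") or {}).items():
        name = {"C1": "Criterion 1", "C2": "Criterion 2"}.get(crit, crit)
        rows[f"{name}: concordant among uniques, n (%)"] = [
            _n_pct(s["n_concordant"], s["n_unique"]) for s in block["per_step"]
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).to_string()
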