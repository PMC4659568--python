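"""Synthetic trial/admissions cohort pairs with known ground truth.

Real trial-to-claims linkages cannot ship with test data (both sources are
protected patient records), so this module generates the two tables with a
controllable discrepancy model and emits the generative links alongside.

The generator emulates the features that matter to indirect-identifier
matching:

* a trial roster of pediatric leukemia patients enrolled at a set of
  hospitals over a fixed trial window, a fraction of whom transferred in
  (their enrollment date is replaced by a transfer date before matching);
* with probability ``p_captured`` a trial patient also appears in the
  admissions table at the same hospital, admitted ``admission_lag_days``
  after the effective enrollment date — a benign lag that can cross month
  or year boundaries;
* with probability ``p_gross_error`` the captured admission's year and/or
  month are re-drawn at random, emulating recording errors in the
  administrative date fields;
* with probability ``p_collision`` a patient is given another patient's
  (site, gender, birth year, birth month) blocking key, emulating the
  attribute collisions that make coarse identifiers non-unique;
* ``n_distractors`` administrative-only leukemia patients drawn from the
  same demographic distributions;
* captured and distractor patients may have repeat admissions
  (``p_readmission``), so collapsing to index records is exercised.

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional

import numpy as np

from .errors import ConfigError
from .records import AdminAdmission, TrialRecord, effective_event_date

__all__ = ["SimConfig", "simulate_pair", "make_worked_fixture"]

#: ICD-9 roots for AML / unspecified leukemia used for qualifying codes
_QUALIFYING_ROOTS = ("205", "206", "207", "208")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort pair.

    Defaults describe a pediatric AML trial: ~400 patients enrolled over a
    four-year window at the full set of participating children's
    hospitals, almost all captured in the administrative source, with a
    modest admission lag, a small gross date-error rate and rare
    blocking-key collisions.
    """

    n_trial: int = 415
    n_sites: int = 44
    window: tuple[date, date] = (date(2006, 8, 14), date(2010, 6, 15))
    p_captured: float = 0.95
    n_distractors: int = 200
    p_transfer: float = 0.05
    admission_lag_days: tuple[int, int] = (0, 21)
    p_gross_error: float = 0.05
    p_collision: float = 0.01
    birth_year_range: tuple[int, int] = (1988, 2005)
    p_readmission: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_captured", "p_transfer", "p_gross_error", "p_collision", "p_readmission"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_trial < 1 or self.n_sites < 1:
            raise ConfigError("n_trial and n_sites must be >= 1")
        if self.n_distractors < 0:
            raise ConfigError("n_distractors must be >= 0")
        start, end = self.window
        if start > end:
            raise ConfigError(f"window start {start} after end {end}")
        lo, hi = self.admission_lag_days
        if lo > hi or lo < 0:
            raise ConfigError(f"admission_lag_days must be 0 <= lo <= hi, got {self.admission_lag_days}")
        by_lo, by_hi = self.birth_year_range
        if by_lo > by_hi:
            raise ConfigError("birth_year_range must be well-ordered")
        if by_hi >= start.year:
            raise ConfigError(
                "birth_year_range must end before the window starts so every "
                f"birth precedes enrollment (got {self.birth_year_range} vs "
                f"window start {start})"
            )


def _rand_date_in(rng: np.random.Generator, start: date, end: date) -> date:
    return start + timedelta(days=int(rng.integers(0, (end - start).days + 1)))


def _clamp_day(year: int, month: int, day: int) -> date:
    return date(year, month, min(day, calendar.monthrange(year, month)[1]))


def _clamp_to_window(d: date, window: tuple[date, date]) -> date:
    start, end = window
    return min(max(d, start), end)


def _gross_error_date(
    rng: np.random.Generator, d: date, window: tuple[date, date], apply: bool
) -> date:
    """Re-draw the year and/or month of ``d`` at random (day kept).

    Draws are consumed even when ``apply`` is False so that two runs
    differing only in ``p_gross_error`` share common random numbers: the
    corrupted run's tables differ from the clean run's only on the
    corrupted records.
    """
    mode = ("month", "year", "both")[int(rng.integers(3))]
    year = int(rng.integers(window[0].year, window[1].year + 1))
    month = int(rng.integers(1, 13))
    if not apply:
        return d
    if mode == "month":
        year = d.year
    elif mode == "year":
        month = d.month
    return _clamp_to_window(_clamp_day(year, month, d.day), window)


def _qualifying_codes(rng: np.random.Generator) -> tuple[str, ...]:
    root = _QUALIFYING_ROOTS[int(rng.integers(len(_QUALIFYING_ROOTS)))]
    code = f"{root}.{int(rng.integers(0, 10))}{int(rng.integers(0, 10))}"
    # occasionally a co-occurring non-leukemia code
    if rng.random() < 0.3:
        return (code, "486")
    return (code,)


def simulate_pair(
    config: SimConfig,
) -> tuple[list[TrialRecord], list[AdminAdmission], dict[str, Optional[str]]]:
    """Generate (trial roster, admissions table, truth links) under ``config``.

    The truth mapping sends each trial id to its administrative patient id,
    or None when the patient was not captured in the administrative source.
    The truth is never consumed by the matcher; it exists for evaluation.
    """
    rng = np.random.default_rng(config.seed)
    start, end = config.window
    sites = [f"S{i:03d}" for i in range(config.n_sites)]

    # Blocking keys (site, gender, birth year, birth month) are sampled
    # without replacement across all generated patients: the collision rate
    # is an experimental condition fully controlled by p_collision, never a
    # sampling accident.
    used_keys: set[tuple[str, str, int, int]] = set()
    n_keys = (
        config.n_sites
        * 2
        * (config.birth_year_range[1] - config.birth_year_range[0] + 1)
        * 12
    )
    if config.n_trial + config.n_distractors > n_keys:
        raise ConfigError(
            f"infeasible config: {config.n_trial + config.n_distractors} patients "
            f"but only {n_keys} distinct (site, gender, birth year/month) keys"
        )

    def draw_demographics():
        while True:
            site = sites[int(rng.integers(len(sites)))]
            gender = "M" if rng.random() < 0.5 else "F"
            by = int(rng.integers(config.birth_year_range[0], config.birth_year_range[1] + 1))
            bm = int(rng.integers(1, 13))
            bd = int(rng.integers(1, 29))
            if (site, gender, by, bm) not in used_keys:
                used_keys.add((site, gender, by, bm))
                return site, gender, date(by, bm, bd)

    trial: list[TrialRecord] = []
    for i in range(config.n_trial):
        site, gender, birth = draw_demographics()
        if trial and rng.random() < config.p_collision:
            other = trial[int(rng.integers(len(trial)))]
            site, gender = other.site_id, other.gender
            birth = _clamp_day(other.birth_year, other.birth_month, birth.day)
        enroll = _rand_date_in(rng, start, end)
        transfer = None
        if rng.random() < config.p_transfer:
            transfer = min(enroll + timedelta(days=int(rng.integers(1, 46))), end)
        trial.append(
            TrialRecord(
                trial_id=f"T{i:04d}",
                site_id=site,
                gender=gender,
                enrollment_date=enroll,
                birth_date=birth,
                transfer_date=transfer,
            )
        )

    admissions: list[AdminAdmission] = []
    truth: dict[str, Optional[str]] = {}

    def add_admissions(admin_id, site, gender, birth, first_admission):
        admissions.append(
            AdminAdmission(
                admin_id=admin_id,
                site_id=site,
                gender=gender,
                admission_date=first_admission,
                icd9_codes=_qualifying_codes(rng),
                birth_date=birth,
            )
        )
        if rng.random() < config.p_readmission:
            later = first_admission + timedelta(days=int(rng.integers(20, 121)))
            admissions.append(
                AdminAdmission(
                    admin_id=admin_id,
                    site_id=site,
                    gender=gender,
                    admission_date=min(later, end),
                    icd9_codes=_qualifying_codes(rng),
                    birth_date=birth,
                )
            )

    lag_lo, lag_hi = config.admission_lag_days
    for i, rec in enumerate(trial):
        if rng.random() >= config.p_captured:
            truth[rec.trial_id] = None
            continue
        admin_id = f"P{i:04d}"
        truth[rec.trial_id] = admin_id
        event = effective_event_date(rec)
        lag = int(rng.integers(lag_lo, lag_hi + 1))
        admission = _clamp_to_window(event + timedelta(days=lag), config.window)
        corrupt = rng.random() < config.p_gross_error
        admission = _gross_error_date(rng, admission, config.window, corrupt)
        add_admissions(admin_id, rec.site_id, rec.gender, rec.birth_date, admission)

    for j in range(config.n_distractors):
        site, gender, birth = draw_demographics()
        if rng.random() < config.p_collision:
            other = trial[int(rng.integers(len(trial)))]
            site, gender = other.site_id, other.gender
            birth = _clamp_day(other.birth_year, other.birth_month, birth.day)
        add_admissions(
            f"D{j:04d}", site, gender, birth, _rand_date_in(rng, start, end)
        )

    return trial, admissions, truth


def make_worked_fixture():
    """Deterministic five-patient fixture with a hand-traced expectation.

    The roster holds patients A–E designed so that, under the default
    four-step schedule, exactly one new unique match appears at each step:

    * ``A`` agrees with its admission on all six variables (step 1);
    * ``B`` differs only in event month (recovered at step 2);
    * ``C``'s admission year is off by three (recovered at step 3, when the
      event year is ignored);
    * ``D``'s admission year is off by one, and a distractor patient shares
      D's site/gender/birth key with an admission five years out — so D is
      ambiguous at step 3 (two candidates) but unique at step 4 (±1 year
      excludes the distractor);
    * ``E`` has no administrative counterpart and never matches.

    Returns ``(trial, admissions, truth, expected)`` where ``expected``
    summarizes the hand trace: per-step unique trial ids, per-record
    per-step classifications, and the cumulative unique count.
    """
    t = [
        TrialRecord("A", "S01", "M", date(2007, 3, 10), birth_date=date(2000, 1, 15)),
        TrialRecord("B", "S01", "F", date(2007, 3, 10), birth_date=date(2001, 6, 2)),
        TrialRecord("C", "S01", "M", date(2007, 3, 10), birth_date=date(1999, 11, 20)),
        TrialRecord("D", "S01", "F", date(2007, 7, 1), birth_date=date(2002, 9, 9)),
        TrialRecord("E", "S01", "M", date(2008, 5, 5), birth_date=date(2003, 3, 3)),
    ]
    a = [
        AdminAdmission("PA", "S01", "M", date(2007, 3, 22), ("205.00",), birth_date=date(2000, 1, 15)),
        AdminAdmission("PB", "S01", "F", date(2007, 4, 5), ("206.10",), birth_date=date(2001, 6, 2)),
        AdminAdmission("PC", "S01", "M", date(2010, 5, 1), ("207.00",), birth_date=date(1999, 11, 20)),
        AdminAdmission("PD", "S01", "F", date(2008, 2, 15), ("208.91",), birth_date=date(2002, 9, 9)),
        # PD's repeat admission: index derivation must keep 2008-02-15
        AdminAdmission("PD", "S01", "F", date(2008, 3, 10), ("205.01",), birth_date=date(2002, 9, 9)),
        # distractor sharing D's blocking key, admission five years out
        AdminAdmission("DX", "S01", "F", date(2012, 6, 30), ("205.00",), birth_date=date(2002, 9, 21)),
    ]
    truth: dict[str, Optional[str]] = {"A": "PA", "B": "PB", "C": "PC", "D": "PD", "E": None}
    expected = {
        "unique_per_step": {1: ["A"], 2: ["B"], 3: ["C"], 4: ["D"]},
        "classifications": {
            ("A", 1): "UNIQUE",
            ("B", 1): "NO_MATCH",
            ("B", 2): "UNIQUE",
            ("C", 1): "NO_MATCH",
            ("C", 2): "NO_MATCH",
            ("C", 3): "UNIQUE",
            ("D", 1): "NO_MATCH",
            ("D", 2): "NO_MATCH",
            ("D", 3): "MULTIPLE_ADMIN",
            ("D", 4): "UNIQUE",
            ("E", 1): "NO_MATCH",
            ("E", 2): "NO_MATCH",
            ("E", 3): "NO_MATCH",
            ("E", 4): "NO_MATCH",
        },
        "final_assignments": {"A": "PA", "B": "PB", "C": "PC", "D": "PD"},
        "n_available_per_step": [5, 4, 3, 2],
        "cumulative_unique": 4,
        "cumulative_unique_pct": 80.0,
    }
    return t, a, truth, expected
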