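from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from steplink import (
    AdminIndexRecord,
    DirectLinkage,
    StepwiseLinkage,
    TrialRecord,
    derive_index_records,
    evaluate_against_truth,
    filter_aml_cohort,
    make_worked_fixture,
)
from steplink.simulate import SimConfig, simulate_pair


@pytest.fixture(scope="session")
def worked():
    """The deterministic five-patient hand-traced fixture."""
    trial, admissions, truth, expected = make_worked_fixture()
    return trial, admissions, truth, expected


@pytest.fixture(scope="session")
def worked_result(worked):
    trial, admissions, _, _ = worked
    index = derive_index_records(admissions)
    return StepwiseLinkage(trial, index).fit()


def simulate_and_match(cfg: SimConfig, steps=None):
    """Run simulate -> cohort filter -> index -> stepwise fit."""
    trial, admissions, truth = simulate_pair(cfg)
    index = derive_index_records(filter_aml_cohort(admissions, cfg.window))
    model = StepwiseLinkage(trial, index) if steps is None else StepwiseLinkage(trial, index, steps)
    return trial, index, truth, model.fit()


def random_small_instance(rng: np.random.Generator):
    """A small, collision-rich random trial/admin pair (<=30 per side).

    Tiny key alphabets force plenty of forward/reverse ambiguity; some
    records are missing matching fields.
    """
    sites = ["S1", "S2"]
    genders = ["M", "F"]
    n_t = int(rng.integers(1, 31))
    n_a = int(rng.integers(0, 31))

    def rand_date(years=(2007, 2009), months=(1, 3)):
        return date(
            int(rng.integers(years[0], years[1] + 1)),
            int(rng.integers(months[0], months[1] + 1)),
            int(rng.integers(1, 29)),
        )

    trial = []
    for i in range(n_t):
        missing = rng.random() < 0.1
        enroll = rand_date()
        trial.append(
            TrialRecord(
                trial_id=f"T{i}",
                site_id=sites[int(rng.integers(2))],
                gender=None if missing else genders[int(rng.integers(2))],
                enrollment_date=enroll,
                birth_date=rand_date(years=(2000, 2002)),
                transfer_date=(
                    enroll.replace(year=enroll.year + 1) if rng.random() < 0.15 else None
                ),
            )
        )
    admin = [
        AdminIndexRecord(
            admin_id=f"A{j}",
            site_id=sites[int(rng.integers(2))],
            gender=None if rng.random() < 0.1 else genders[int(rng.integers(2))],
            admission_date=rand_date(years=(2006, 2011)),
            birth_date=rand_date(years=(2000, 2002)),
        )
        for j in range(n_a)
    ]
    return trial, admin
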